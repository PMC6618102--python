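"""Stage 2: broadband entrainment of the cortical response.

For every participant and presentation rate, compares the induced
(baselined) amplitude at the rate's own band between trials presented at
that rate (matched) and an equal-count random sample of trials presented
at the other eleven rates (unmatched), using the rate-specific active /
baseline windows.  Chauvenet's criterion (0.5) screens participants on
the mean matched-unmatched difference; survivors enter the 2 x 12
repeated-measures ANOVA.

Usage: python analysis/04_entrainment.py
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from importlib import import_module

decompose = import_module("02_decompose")

from burstcount import run_entrainment_stage
from burstcount.io import write_result

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    study, cfg = decompose.load_study()
    result = run_entrainment_stage(study, seed=cfg.stage_seed("entrainment"))
    a = result.anova
    d = result.matched_minus_unmatched()
    print(f"matched - unmatched induced amplitude, mean over rates: {d.mean():.3g}")
    print(f"excluded by Chauvenet: {result.excluded or 'none'}")
    print(f"main effect F({a.df_main[0]},{a.df_main[1]}) = {a.f_main:.2f}, "
          f"p = {a.p_main:.4g}, BF10 = {a.bf_main.bf10:.2f}")
    print(f"rate interaction F({a.df_interaction[0]},{a.df_interaction[1]}) "
          f"= {a.f_interaction:.2f}, p = {a.p_interaction:.3g}")
    write_result(result.to_dict(), ROOT / "results" / "entrainment.json",
                 config_hash=cfg.config_hash())
    print("wrote results/entrainment.json")


if __name__ == "__main__":
    main()
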