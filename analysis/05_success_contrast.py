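"""Stage 3: successful vs unsuccessful counting contrast.

Pools the high-prevalence (10 and 14 Hz) trials, equalises success /
failure trial counts per participant (one seeded down-sampling), and runs
four max-cluster-mass permutation analyses over the frequency x time
grid: raw amplitude, baselined amplitude, PLV difference (paired t maps,
sign-flip null, per-permutation Chauvenet) and circular-mean phase angle
(Watson's U2, label-swap null).  Group-level Rayleigh maps are computed
per condition.

The full 3-100 Hz grid at 5,000 permutations takes a few minutes; pass a
smaller permutation count as the first argument for a quick look.

Usage: python analysis/05_success_contrast.py [n_permutations]
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from importlib import import_module

decompose = import_module("02_decompose")

from burstcount import run_success_contrast_stage
from burstcount.io import write_result

ROOT = Path(__file__).resolve().parents[1]


def main(n_permutations: int = 5000) -> None:
    study, cfg = decompose.load_study()
    result = run_success_contrast_stage(
        study, seed=cfg.stage_seed("success_contrast"),
        n_permutations=n_permutations)
    print(f"equal-n trials per condition: mean "
          f"{result.trial_counts.mean():.1f} (min {result.trial_counts.min()})")
    for name in ("phase_angle", "amplitude_raw", "amplitude_baselined",
                 "plv_difference"):
        res = getattr(result, name)
        sig = res.significant(0.05)
        print(f"{name}: {len(res.clusters)} clusters, {len(sig)} significant")
        for c in sig[:3]:
            fs = [result.frequencies[fi] for fi, _ in c.bins]
            ts = [result.times[ti] for _, ti in c.bins]
            print(f"  p = {c.p_value:.4f}, {min(fs):.0f}-{max(fs):.0f} Hz, "
                  f"{min(ts)*1000:.0f}..{max(ts)*1000:.0f} ms, sign {c.sign:+d}")
    write_result(result.to_dict(), ROOT / "results" / "success_contrast.json",
                 config_hash=cfg.config_hash())
    print("wrote results/success_contrast.json")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 5000)
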