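"""Stage 1: correlation between oscillatory amplitude spectra and behaviour.

Normalizes each participant's amplitude spectrum and accuracy profile
(min subtracted, range divided) and fits the within-subject ANCOVA with
participants partialled out.  Reports the common slope, within-subject r,
the slope F test, and the intercept test with its JZS Bayes factor (a
BF10 < 1/3 supports the one-to-one overlay of the two spectra).

Usage: python analysis/03_correlation.py
"""

from pathlib import Path

import pandas as pd

from burstcount.io import read_config, read_trials, require_artifact, write_result
from burstcount.stages import behavioural_profiles, correlation_from_profiles

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cfg = read_config(require_artifact(ROOT / "results" / "config.yaml",
                                       "analysis/01_simulate.py"))
    schedule = read_trials(require_artifact(ROOT / "scratch" / "trials.csv",
                                            "analysis/01_simulate.py"))
    spec = pd.read_csv(require_artifact(ROOT / "results" / "spectral_profiles.csv",
                                        "analysis/02_decompose.py"),
                       index_col="participant")
    spec.columns = spec.columns.astype(int)

    result = correlation_from_profiles(spec, behavioural_profiles(schedule))
    a = result.ancova
    print(f"within-subject correlation r = {a.r:.3f}")
    print(f"slope = {a.slope:.3f} (SE {a.slope_se:.3f}), "
          f"F({a.slope_df[0]},{a.slope_df[1]}) = {a.slope_f:.2f}, p = {a.slope_p:.3g}")
    print(f"intercept = {a.intercept_mean:.4f} (SE {a.intercept_se:.4f}), "
          f"T{a.intercept_df} = {a.intercept_t:.2f}, p = {a.intercept_p:.3g}, "
          f"BF10 = {a.intercept_bf.bf10:.2f}")
    print(f"participant factor F({a.participant_df[0]},{a.participant_df[1]}) "
          f"= {a.participant_f:.2f}, p = {a.participant_p:.3g}")

    write_result(result.to_dict(), ROOT / "results" / "correlation.json",
                 config_hash=cfg.config_hash())
    print("wrote results/correlation.json")


if __name__ == "__main__":
    main()
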