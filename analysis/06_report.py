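"""Collate the three stage results into one summary document and figures.

Usage: python analysis/06_report.py
"""

from pathlib import Path

import json

from burstcount.io import read_result, require_artifact, write_result

ROOT = Path(__file__).resolve().parents[1]

STAGES = {
    "correlation": "analysis/03_correlation.py",
    "entrainment": "analysis/04_entrainment.py",
    "success_contrast": "analysis/05_success_contrast.py",
}


def main() -> None:
    summary = {}
    for stage, producer in STAGES.items():
        doc = read_result(require_artifact(ROOT / "results" / f"{stage}.json",
                                           producer))
        summary[f"{stage}_config_hash"] = doc.get("config_hash")
        if stage == "correlation":
            a = doc["ancova"]
            summary["correlation"] = {
                "r": a["r"], "slope": a["slope"],
                "slope_f": a["slope_f"], "slope_df": a["slope_df"],
                "slope_p": a["slope_p"],
                "intercept": a["intercept_mean"], "intercept_t": a["intercept_t"],
                "intercept_bf10": a["intercept_bf10"],
            }
        elif stage == "entrainment":
            a = doc["anova"]
            summary["entrainment"] = {
                "f_main": a["f_main"], "df_main": a["df_main"],
                "p_main": a["p_main"], "bf10_main": a["bf10_main"],
                "f_interaction": a["f_interaction"],
                "p_interaction": a["p_interaction"],
                "excluded": doc["excluded_participants"],
            }
        else:
            summary["success_contrast"] = {
                name: [
                    {"p": c["p_value"], "sign": c["sign"], "n_bins": c["n_bins"]}
                    for c in doc[name]["clusters"] if c["p_value"] < 0.05
                ]
                for name in ("phase_angle", "amplitude_raw",
                             "amplitude_baselined", "plv_difference")
            }
    write_result({"stage": "report", **summary}, ROOT / "results" / "report.json")
    print(json.dumps(summary, indent=2))
    print("wrote results/report.json")


if __name__ == "__main__":
    main()
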