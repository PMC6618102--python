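"""Simulate one full synthetic study.

Builds the balanced trial schedule (20 participants x 4 blocks x 144
trials), draws per-participant 1/f background profiles, simulates
behaviour coupled to those profiles, and synthesises virtual-sensor
epochs with the default ground-truth effects (entrainment gain 1, gamma
phase/success coupling).  Writes the trial table and config under
results/ and the epoch container under scratch/ (it is large and
regenerable).

Usage: python analysis/01_simulate.py [master_seed]
"""

import sys
from pathlib import Path

from burstcount import simulate_study
from burstcount.io import RunConfig, write_config, write_epochs, write_trials

ROOT = Path(__file__).resolve().parents[1]


def main(master_seed: int = 1) -> RunConfig:
    cfg = RunConfig(master_seed=master_seed)
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "scratch").mkdir(exist_ok=True)

    study = simulate_study(cfg.truth, cfg.n_participants, cfg.n_blocks,
                           cfg.base_reps, cfg.high_prev_reps,
                           seed=cfg.stage_seed("simulate"))
    n = len(study.schedule)
    acc = study.schedule["correct"].mean()
    print(f"simulated {cfg.n_participants} participants, {n} trials "
          f"({n // cfg.n_participants}/participant), overall accuracy {acc:.3f}")

    write_config(cfg, ROOT / "results" / "config.yaml")
    write_trials(study.schedule, ROOT / "scratch" / "trials.csv")
    write_epochs(study.epochs, ROOT / "scratch" / "epochs.h5",
                 seed=cfg.master_seed)
    print("wrote scratch/trials.csv, results/config.yaml, scratch/epochs.h5")
    return cfg


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
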