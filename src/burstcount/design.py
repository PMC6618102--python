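"""Experimental design: burst-train stimuli and the trial schedule.

The task presents trains of 4-7 white-noise bursts at one of twelve
presentation rates (3-38 Hz); the participant counts the bursts.  A block
contains 144 trials: ten base-rate frequencies presented 8 times each and
two high-prevalence frequencies (10 and 14 Hz) presented 32 times each,
with the four burst counts equally prevalent within every frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PRESENTATION_FREQUENCIES: tuple[int, ...] = (3, 4, 6, 8, 10, 12, 14, 16, 18, 22, 28, 38)
HIGH_PREVALENCE_FREQUENCIES: tuple[int, ...] = (10, 14)
BURST_COUNTS: tuple[int, ...] = (4, 5, 6, 7)

#: Epoch sampling conventions for the virtual sensor.
SAMPLING_RATE: float = 1200.0
EPOCH_START: float = -0.8
EPOCH_N_SAMPLES: int = 1920  # covers [-800, 800) ms, half-open
AUDIO_OFFSET: float = 0.030  # stimulus reaches the ear 30 ms after the trigger

SCHEDULE_COLUMNS = [
    "participant", "block", "frequency", "n_bursts", "response", "correct", "rejected",
]


class InvalidDesignError(ValueError):
    """Raised when repetition counts cannot honour the balanced design."""


def epoch_times(n_samples: int = EPOCH_N_SAMPLES, fs: float = SAMPLING_RATE,
                t_start: float = EPOCH_START) -> np.ndarray:
    """Epoch time axis in seconds, half-open on the right."""
    return t_start + np.arange(n_samples) / fs


@dataclass(frozen=True)
class StimulusTrain:
    """Rectangular burst-train envelope description.

    Burst k (0-based) starts at ``k / frequency`` and lasts
    ``duty_cycle / frequency`` seconds.
    """

    frequency: float
    n_bursts: int
    duty_cycle: float = 0.5
    onsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if not 4 <= self.n_bursts <= 7:
            raise ValueError("n_bursts must be between 4 and 7")
        if not 0 < self.duty_cycle <= 1:
            raise ValueError("duty_cycle must lie in (0, 1]")
        object.__setattr__(
            self, "onsets", np.arange(self.n_bursts) / self.frequency)

    @property
    def wavelength(self) -> float:
        return 1.0 / self.frequency

    @property
    def burst_duration(self) -> float:
        return self.duty_cycle / self.frequency

    @property
    def end(self) -> float:
        """End of the final burst: (n_bursts - 1 + duty_cycle) * wavelength."""
        return (self.n_bursts - 1 + self.duty_cycle) / self.frequency

    def envelope(self, times: np.ndarray, onset_time: float = 0.0) -> np.ndarray:
        """Evaluate the 0/1 envelope on an arbitrary time axis.

        ``onset_time`` shifts the train so its first burst starts there
        (used to place stimuli at the +30 ms audio-offset epoch time).
        """
        t = np.asarray(times) - onset_time
        phase = t * self.frequency
        in_cycle = (phase >= 0) & (phase < self.n_bursts)
        within_burst = (phase - np.floor(phase)) < self.duty_cycle
        return (in_cycle & within_burst).astype(float)


def synthesize_stimulus_train(frequency: float, n_bursts: int,
                              duty_cycle: float = 0.5,
                              sampling_rate: float = SAMPLING_RATE,
                              ) -> tuple[StimulusTrain, np.ndarray, np.ndarray]:
    """Burst-train envelope sampled from t=0 to the end of the final burst.

    Returns ``(train, times, envelope)`` where the envelope is 1 inside
    bursts and 0 in the silent gaps.
    """
    train = StimulusTrain(frequency, n_bursts, duty_cycle)
    n = int(np.ceil(train.end * sampling_rate))
    times = np.arange(n) / sampling_rate
    return train, times, train.envelope(times)


def build_trial_schedule(n_participants: int = 20, n_blocks: int = 4,
                         base_reps: int = 8, high_prev_reps: int = 32,
                         seed: int = 0) -> pd.DataFrame:
    """Build the full balanced trial schedule.

    Every block presents each base frequency ``base_reps`` times and the
    high-prevalence frequencies (10, 14 Hz) ``high_prev_reps`` times, with
    the four burst conditions equally prevalent within each frequency.
    Trial order is randomised independently per block.

    Responses are initialised missing; :func:`burstcount.simulate.simulate_behaviour`
    fills them in.
    """
    for name, reps in (("base_reps", base_reps), ("high_prev_reps", high_prev_reps)):
        if reps <= 0 or reps % len(BURST_COUNTS):
            raise InvalidDesignError(
                f"{name}={reps} is not a positive multiple of "
                f"{len(BURST_COUNTS)} burst conditions")
    if n_participants < 1 or n_blocks < 1:
        raise InvalidDesignError("need at least one participant and one block")

    rng = np.random.default_rng(seed)
    cell_freq, cell_bursts = [], []
    for f in PRESENTATION_FREQUENCIES:
        reps = high_prev_reps if f in HIGH_PREVALENCE_FREQUENCIES else base_reps
        for b in BURST_COUNTS:
            cell_freq.extend([f] * (reps // len(BURST_COUNTS)))
            cell_bursts.extend([b] * (reps // len(BURST_COUNTS)))
    cell_freq = np.asarray(cell_freq)
    cell_bursts = np.asarray(cell_bursts)

    frames = []
    for p in range(n_participants):
        for blk in range(1, n_blocks + 1):
            order = rng.permutation(len(cell_freq))
            frames.append(pd.DataFrame({
                "participant": p,
                "block": blk,
                "frequency": cell_freq[order],
                "n_bursts": cell_bursts[order],
            }))
    schedule = pd.concat(frames, ignore_index=True)
    schedule["response"] = pd.array([pd.NA] * len(schedule), dtype="Int64")
    schedule["correct"] = False
    schedule["rejected"] = False
    return schedule


def validate_schedule(schedule: pd.DataFrame) -> None:
    """Raise if the schedule violates the design invariants."""
    missing = set(SCHEDULE_COLUMNS) - set(schedule.columns)
    if missing:
        raise InvalidDesignError(f"schedule missing columns: {sorted(missing)}")
    bad = set(schedule["frequency"].unique()) - set(PRESENTATION_FREQUENCIES)
    if bad:
        raise InvalidDesignError(f"unknown presentation frequencies: {sorted(bad)}")
    answered = schedule["response"].notna()
    if answered.any():
        eq = schedule.loc[answered, "response"] == schedule.loc[answered, "n_bursts"]
        if not (schedule.loc[answered, "correct"] == eq).all():
            raise InvalidDesignError("correct flag inconsistent with response == n_bursts")
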