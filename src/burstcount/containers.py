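"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import AUDIO_OFFSET, EPOCH_N_SAMPLES, EPOCH_START, SAMPLING_RATE, epoch_times


@dataclass
class EpochArray:
    """Per-trial virtual-sensor time series.

    ``data`` has shape (n_trials, n_samples); the time axis is half-open,
    [-800, 800) ms at 1,200 Hz by default.  ``audio_offset`` records when
    the stimulus actually reaches the ear relative to the trigger.
    """

    data: np.ndarray
    fs: float = SAMPLING_RATE
    t_start: float = EPOCH_START
    audio_offset: float = AUDIO_OFFSET
    times: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.times = epoch_times(self.data.shape[1], self.fs, self.t_start)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def onset(self) -> float:
        """Stimulus onset in epoch time (trigger + audio offset)."""
        return self.audio_offset

    def __len__(self) -> int:
        return self.n_trials


@dataclass
class TFDecomposition:
    """Hilbert filter-bank decomposition: trial x frequency x time.

    ``amplitude`` is the modulus and ``phase`` the argument of the analytic
    signal in each band.  ``amplitude`` may be baselined (then negative
    values are meaningful deviations, see ``baselined``).
    """

    amplitude: np.ndarray
    phase: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray
    baselined: bool = False

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase shapes differ")
        if self.amplitude.shape[1] != self.frequencies.size:
            raise ValueError("frequency axis mismatch")
        if self.amplitude.shape[2] != self.times.size:
            raise ValueError("time axis mismatch")

    def band_index(self, frequency: float) -> int:
        """Nearest-centre band lookup (all presentation rates are on-grid)."""
        return int(np.argmin(np.abs(self.frequencies - frequency)))

    def time_slice(self, window: tuple[float, float]) -> slice:
        start, end = window
        if start >= end:
            raise ValueError("window start must precede end")
        i0 = int(np.searchsorted(self.times, start - 1e-12))
        i1 = int(np.searchsorted(self.times, end + 1e-12))
        if i0 >= i1:
            raise ValueError(f"window {window} contains no samples")
        return slice(i0, i1)
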