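"""Synthetic virtual-sensor data with controllable ground-truth effects.

Each epoch is the sum of four components:

* a 1/f-amplitude Gaussian background (spectral amplitude ``f**-alpha``),
  the "prevalence of oscillatory activity" the correlation analysis reads;
* an induced oscillation at the trial's presentation rate, gated by the
  burst-train envelope and scaled by the entrainment gain ``g`` relative
  to the background RMS in the matching 6 Hz band;
* a phase-locked evoked transient (damped sinusoid) at stimulus onset;
* a gamma-band oscillation whose prestimulus phase is drawn von Mises
  around a preferred angle on to-be-successful trials and around the
  opposite angle otherwise, and whose amplitude is scaled down before /
  up after stimulus onset on successful trials.

Behavioural accuracy is coupled to the participant's *true* normalized
amplitude profile at the twelve presentation rates, floored at the 0.25
guessing rate of the four-alternative count response.  Setting
``entrainment_gain = 0`` together with :meth:`GroundTruth.null` couplings
produces pure null data for calibration runs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field, replace

import numpy as np
import pandas as pd

from .containers import EpochArray
from .design import (
    AUDIO_OFFSET,
    BURST_COUNTS,
    EPOCH_N_SAMPLES,
    EPOCH_START,
    PRESENTATION_FREQUENCIES,
    SAMPLING_RATE,
    StimulusTrain,
    build_trial_schedule,
    epoch_times,
)

__all__ = [
    "GroundTruth",
    "ParticipantProfile",
    "Study",
    "draw_profiles",
    "simulate_behaviour",
    "simulate_study",
    "synthesize_epochs",
]


@dataclass(frozen=True)
class GroundTruth:
    """All generator parameters, recorded alongside every simulated study.

    Amplitudes are expressed relative to background levels so the same
    settings behave comparably across participants: ``entrainment_gain``
    and ``gamma_amplitude`` multiply the background RMS of the matching
    6 Hz band, ``evoked_amplitude`` multiplies the broadband SD.
    """

    background_exponent: float = 1.0       # alpha of the 1/f amplitude spectrum
    background_scale: float = 1.0          # arbitrary source-amplitude units
    alpha_sd: float = 0.05                 # between-participant exponent spread
    profile_jitter_sd: float = 0.05        # log-amplitude spectral jitter per participant

    entrainment_gain: float = 1.0          # g: induced RMS / background band RMS
    evoked_amplitude: float = 1.5
    evoked_frequency: float = 8.0
    evoked_decay: float = 0.06             # seconds

    gamma_frequency: float = 71.0          # centre of the 66-77 Hz band of interest
    gamma_band: tuple[float, float] = (66.0, 77.0)
    gamma_amplitude: float = 2.0           # prestimulus gamma RMS / band RMS
    gamma_success_prestim: float = 0.6     # prestim desynchronisation on success
    gamma_success_poststim: float = 1.6    # poststim synchronisation on success
    gamma_preferred_phase: float = 0.0     # success phase angle; failures sit ~pi away
    gamma_phase_concentration: float = 2.0 # von Mises kappa; 0 = uniform

    behaviour_coupling: float = 1.0        # P(correct) = floor + (1-floor)*c*x_norm
    guess_floor: float = 0.25

    duty_cycle: float = 0.5
    audio_offset: float = AUDIO_OFFSET

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gamma_band"] = list(self.gamma_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        if "gamma_band" in d:
            d["gamma_band"] = tuple(d["gamma_band"])
        return cls(**d)

    @classmethod
    def null(cls, **overrides) -> "GroundTruth":
        """No injected effects: downstream stages should find nothing."""
        base = dict(
            entrainment_gain=0.0,
            gamma_success_prestim=1.0,
            gamma_success_poststim=1.0,
            gamma_phase_concentration=0.0,
            behaviour_coupling=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class ParticipantProfile:
    """One participant's true background spectrum.

    Spectral amplitude at frequency f is
    ``scale * max(f, 1)**-alpha * exp(jitter(f))`` with the jitter a
    log-linear interpolation of per-anchor offsets.
    """

    alpha: float
    scale: float
    anchor_freqs: np.ndarray
    anchor_log_jitter: np.ndarray

    def spectral_amplitude(self, freqs: np.ndarray) -> np.ndarray:
        f = np.maximum(np.asarray(freqs, dtype=float), 1.0)
        jit = np.interp(np.log(f), np.log(self.anchor_freqs), self.anchor_log_jitter)
        return self.scale * f ** (-self.alpha) * np.exp(jit)

    def band_rms(self, centre: float, half_bandwidth: float = 3.0,
                 n_samples: int = EPOCH_N_SAMPLES, fs: float = SAMPLING_RATE) -> float:
        """Background RMS inside [centre-hb, centre+hb], from the same
        discrete spectrum the generator draws from."""
        f = np.fft.rfftfreq(n_samples, 1.0 / fs)
        sigma = self.spectral_amplitude(f)
        sigma[0] = 0.0
        in_band = (f >= centre - half_bandwidth) & (f <= centre + half_bandwidth)
        return float(np.sqrt(4.0 * np.sum(sigma[in_band] ** 2) / n_samples ** 2))

    def total_sd(self, f_lo: float = 1.0, f_hi: float = 100.0,
                 n_samples: int = EPOCH_N_SAMPLES, fs: float = SAMPLING_RATE) -> float:
        f = np.fft.rfftfreq(n_samples, 1.0 / fs)
        sigma = self.spectral_amplitude(f)
        sigma[0] = 0.0
        keep = (f >= f_lo) & (f <= f_hi)
        return float(np.sqrt(4.0 * np.sum(sigma[keep] ** 2) / n_samples ** 2))

    def amplitude_profile(self, freqs=PRESENTATION_FREQUENCIES) -> np.ndarray:
        """Expected mean Hilbert envelope at each rate (sqrt(pi/2) * band RMS)."""
        return np.array([np.sqrt(np.pi / 2.0) * self.band_rms(f) for f in freqs])


def draw_profiles(truth: GroundTruth, n_participants: int, seed: int) -> list[ParticipantProfile]:
    rng = np.random.default_rng(seed)
    anchors = np.array([1.0, *PRESENTATION_FREQUENCIES, 100.0])
    profiles = []
    for _ in range(n_participants):
        alpha = rng.normal(truth.background_exponent, truth.alpha_sd)
        jit = rng.normal(0.0, truth.profile_jitter_sd, anchors.size)
        profiles.append(ParticipantProfile(
            alpha=alpha, scale=truth.background_scale,
            anchor_freqs=anchors, anchor_log_jitter=jit))
    return profiles


def _background(rng: np.random.Generator, profile: ParticipantProfile,
                n_trials: int, n_samples: int, fs: float) -> np.ndarray:
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    sigma = profile.spectral_amplitude(f)
    sigma[0] = 0.0
    coeffs = sigma * (rng.standard_normal((n_trials, f.size))
                      + 1j * rng.standard_normal((n_trials, f.size)))
    return np.fft.irfft(coeffs, n=n_samples, axis=1)


def synthesize_epochs(trials: pd.DataFrame, truth: GroundTruth,
                      profile: ParticipantProfile, seed: int,
                      n_samples: int = EPOCH_N_SAMPLES,
                      fs: float = SAMPLING_RATE) -> EpochArray:
    """Generate one participant's epochs for the given trial rows.

    The ``correct`` column carries the planned success state used for the
    gamma phase/amplitude coupling, so behaviour must be simulated first
    (uncoupled configurations ignore it).  Fully deterministic under
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_trials = len(trials)
    times = epoch_times(n_samples, fs)
    onset = truth.audio_offset

    data = _background(rng, profile, n_trials, n_samples, fs)

    freqs = trials["frequency"].to_numpy(dtype=float)
    bursts = trials["n_bursts"].to_numpy(dtype=int)
    success = trials["correct"].to_numpy(dtype=bool)

    # induced component, gated by the burst envelope, random phase per trial
    if truth.entrainment_gain > 0:
        phase = rng.uniform(0, 2 * np.pi, n_trials)
        band_rms = {f: profile.band_rms(f) for f in np.unique(freqs)}
        for i in range(n_trials):
            train = StimulusTrain(freqs[i], bursts[i], truth.duty_cycle)
            env = train.envelope(times, onset_time=onset)
            amp = truth.entrainment_gain * np.sqrt(2.0) * band_rms[freqs[i]]
            data[i] += amp * env * np.sin(
                2 * np.pi * freqs[i] * (times - onset) + phase[i])

    # evoked transient, identical phase across trials
    if truth.evoked_amplitude > 0:
        rel = times - onset
        gate = (rel >= 0).astype(float)
        evoked = (truth.evoked_amplitude * profile.total_sd()
                  * gate * np.exp(-np.clip(rel, 0, None) / truth.evoked_decay)
                  * np.sin(2 * np.pi * truth.evoked_frequency * rel))
        data += evoked[None, :]

    # gamma component: success-conditional prestimulus phase and amplitude
    if truth.gamma_amplitude > 0:
        mu = np.where(success, truth.gamma_preferred_phase,
                      truth.gamma_preferred_phase + np.pi)
        kappa = truth.gamma_phase_concentration
        if kappa > 0:
            phi0 = rng.vonmises(mu, kappa)
        else:
            phi0 = rng.uniform(-np.pi, np.pi, n_trials)
        pre = np.where(success, truth.gamma_success_prestim, 1.0)
        post = np.where(success, truth.gamma_success_poststim, 1.0)
        # 20 ms sigmoid hand-over from the pre- to the post-stimulus level
        trans = 1.0 / (1.0 + np.exp(-(times - onset) / 0.005))
        level = pre[:, None] + (post - pre)[:, None] * trans[None, :]
        amp = (truth.gamma_amplitude * np.sqrt(2.0)
               * profile.band_rms(truth.gamma_frequency))
        carrier = np.cos(2 * np.pi * truth.gamma_frequency * (times - onset)[None, :]
                         + phi0[:, None])
        data += amp * level * carrier

    return EpochArray(data, fs=fs, t_start=EPOCH_START, audio_offset=onset)


def success_probability(trials: pd.DataFrame, profile: ParticipantProfile,
                        truth: GroundTruth) -> np.ndarray:
    """P(correct) per trial: guessing floor plus the amplitude coupling."""
    prof = profile.amplitude_profile()
    rng_ = prof.max() - prof.min()
    x_norm = (prof - prof.min()) / rng_ if rng_ > 0 else np.zeros_like(prof)
    lookup = dict(zip(PRESENTATION_FREQUENCIES, x_norm))
    x = trials["frequency"].map(lookup).to_numpy(dtype=float)
    p = truth.guess_floor + (1 - truth.guess_floor) * truth.behaviour_coupling * x
    return np.clip(p, truth.guess_floor, 1.0)


def simulate_behaviour(schedule: pd.DataFrame, profiles: list[ParticipantProfile],
                       truth: GroundTruth, seed: int) -> pd.DataFrame:
    """Fill responses into the schedule.

    P(correct) is an affine (hence monotone) function of the participant's
    normalized true amplitude at the trial's rate, floored at 0.25 (four
    response options).  Wrong answers are drawn uniformly from the three
    remaining options.  The gamma-phase side of success is realised jointly
    when epochs are synthesised: phases are drawn conditionally on the
    outcomes planned here.
    """
    rng = np.random.default_rng(seed)
    schedule = schedule.copy()
    for p, sub in schedule.groupby("participant"):
        prob = success_probability(sub, profiles[int(p)], truth)
        correct = rng.random(len(sub)) < prob
        n_bursts = sub["n_bursts"].to_numpy(dtype=int)
        response = n_bursts.copy()
        wrong = ~correct
        if wrong.any():
            options = np.array([[b for b in BURST_COUNTS if b != nb]
                                for nb in n_bursts[wrong]])
            pick = rng.integers(0, options.shape[1], wrong.sum())
            response[wrong] = options[np.arange(wrong.sum()), pick]
        schedule.loc[sub.index, "response"] = response
        schedule.loc[sub.index, "correct"] = correct
    schedule["response"] = schedule["response"].astype("Int64")
    return schedule


@dataclass
class Study:
    """A fully simulated study: design, behaviour, and epochs."""

    schedule: pd.DataFrame
    epochs: dict[int, EpochArray]
    profiles: list[ParticipantProfile]
    truth: GroundTruth
    seed: int

    @property
    def participants(self) -> list[int]:
        return sorted(self.epochs)

    def participant_trials(self, participant: int) -> pd.DataFrame:
        return self.schedule[self.schedule["participant"] == participant]


def simulate_study(truth: GroundTruth | None = None, n_participants: int = 20,
                   n_blocks: int = 4, base_reps: int = 8, high_prev_reps: int = 32,
                   seed: int = 0, frequencies: list[float] | None = None) -> Study:
    """End-to-end generation: schedule -> behaviour -> epochs.

    ``frequencies`` optionally restricts which trials get epochs (the
    success-contrast stage only consumes the high-prevalence rates), which
    keeps targeted simulations cheap; the full schedule and behaviour are
    always generated.
    """
    truth = truth or GroundTruth()
    rng = np.random.default_rng(seed)
    s_sched, s_prof, s_beh = rng.integers(0, 2**31, 3)
    schedule = build_trial_schedule(n_participants, n_blocks, base_reps,
                                    high_prev_reps, seed=int(s_sched))
    profiles = draw_profiles(truth, n_participants, int(s_prof))
    schedule = simulate_behaviour(schedule, profiles, truth, int(s_beh))

    epochs: dict[int, EpochArray] = {}
    for p in range(n_participants):
        trials = schedule[schedule["participant"] == p]
        if frequencies is not None:
            trials = trials[trials["frequency"].isin(frequencies)]
        epochs[p] = synthesize_epochs(trials, truth, profiles[p],
                                      seed=int(rng.integers(0, 2**31)))
    if frequencies is not None:
        schedule = schedule[schedule["frequency"].isin(frequencies)].reset_index(drop=True)
    return Study(schedule=schedule, epochs=epochs, profiles=profiles,
                 truth=truth, seed=seed)
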