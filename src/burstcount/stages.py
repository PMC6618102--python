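"""The three analysis stages.

1. Correlation: does behavioural counting accuracy track the participant's
   oscillatory amplitude spectrum across presentation rates?  Normalized
   accuracy and normalized active-window Hilbert amplitude at the twelve
   rates enter a within-subject ANCOVA; the intercept's Bayes factor
   quantifies the one-to-one overlay of the two spectra.
2. Entrainment: is the induced (baselined) amplitude at the presentation
   rate larger when the band matches the rate actually presented than when
   the same band is read from trials presented at other rates?  Matched and
   unmatched point values (equal trial counts, per-rate windows) enter a
   2 x 12 repeated-measures ANOVA after Chauvenet exclusion.
3. Success contrast: do amplitude, phase consistency (PLV) and phase angle
   in the high-prevalence trials differ between successfully and
   unsuccessfully counted trials?  Four max-cluster-mass permutation
   analyses over the frequency x time grid, plus per-condition group-level
   Rayleigh maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circstats import circ_mean, plv, rayleigh_map
from .design import HIGH_PREVALENCE_FREQUENCIES, PRESENTATION_FREQUENCIES
from .inference import (
    AncovaResult,
    ClusterResult,
    RmAnovaResult,
    chauvenet,
    cluster_permutation,
    rm_anova_2x12,
    within_subject_ancova,
)
from .simulate import Study
from .spectral import (
    ACTIVE_WINDOW,
    FREQ_GRID,
    apply_baseline,
    entrainment_windows,
    hilbert_tf,
    window_mean_amplitude,
)

log = logging.getLogger(__name__)

PRESENTATION_BANDS = np.asarray(PRESENTATION_FREQUENCIES, dtype=float)


def normalize_profile(values) -> np.ndarray:
    """Min-subtracted, range-divided profile: min -> 0, max -> 1."""
    values = np.asarray(values, dtype=float)
    rng = values.max() - values.min()
    if rng <= 0:
        raise ValueError("cannot normalize a zero-range profile")
    return (values - values.min()) / rng


# ---------------------------------------------------------------------------
# Stage 1: correlation between oscillatory activity and behaviour

@dataclass
class CorrelationResult:
    spectral: pd.DataFrame       # participant x frequency, raw mean amplitude
    behavioural: pd.DataFrame    # participant x frequency, proportion correct
    spectral_norm: pd.DataFrame
    behavioural_norm: pd.DataFrame
    ancova: AncovaResult

    def to_dict(self) -> dict:
        return {
            "stage": "correlation",
            "ancova": self.ancova.to_dict(),
            "spectral_profiles": self.spectral.to_dict(orient="index"),
            "behavioural_profiles": self.behavioural.to_dict(orient="index"),
        }


def behavioural_profiles(schedule: pd.DataFrame) -> pd.DataFrame:
    """Proportion correct per participant and presentation frequency."""
    usable = schedule[~schedule["rejected"]]
    if usable["response"].isna().any():
        raise ValueError("behavioural responses missing; run simulate_behaviour first")
    acc = (usable.groupby(["participant", "frequency"])["correct"]
           .mean().unstack("frequency"))
    missing = set(PRESENTATION_FREQUENCIES) - set(acc.columns)
    if missing or acc.isna().any().any():
        raise ValueError(f"missing frequency cells in behaviour: {sorted(missing)}")
    return acc[list(PRESENTATION_FREQUENCIES)]


def spectral_profiles(study: Study, decimate: int = 12) -> pd.DataFrame:
    """Mean active-window Hilbert amplitude at the twelve rates, per
    participant, across all usable trials (no prestimulus baseline)."""
    rows = {}
    for p in study.participants:
        keep = ~study.participant_trials(p)["rejected"].to_numpy()
        tf = hilbert_tf(study.epochs[p], frequencies=PRESENTATION_BANDS,
                        decimate=decimate)
        rows[p] = [window_mean_amplitude(tf, ACTIVE_WINDOW, f)[keep].mean()
                   for f in PRESENTATION_BANDS]
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(PRESENTATION_FREQUENCIES))


def correlation_from_profiles(spectral: pd.DataFrame,
                              behavioural: pd.DataFrame) -> CorrelationResult:
    """Normalize both participant profiles and run the within-subject ANCOVA."""
    behavioural = behavioural.loc[spectral.index]
    spec_n = spectral.apply(lambda r: normalize_profile(r.to_numpy()),
                            axis=1, result_type="broadcast")
    beh_n = behavioural.apply(lambda r: normalize_profile(r.to_numpy()),
                              axis=1, result_type="broadcast")
    x = spec_n.to_numpy().ravel()
    y = beh_n.to_numpy().ravel()
    labels = np.repeat(spectral.index.to_numpy(), spectral.shape[1])
    ancova = within_subject_ancova(x, y, labels)
    return CorrelationResult(spectral=spectral, behavioural=behavioural,
                             spectral_norm=spec_n, behavioural_norm=beh_n,
                             ancova=ancova)


def run_correlation_stage(study: Study, decimate: int = 12) -> CorrelationResult:
    spectral = spectral_profiles(study, decimate=decimate)
    return correlation_from_profiles(spectral, behavioural_profiles(study.schedule))


# ---------------------------------------------------------------------------
# Stage 2: entrainment of the cortical response

@dataclass
class EntrainmentResult:
    table: pd.DataFrame          # participant x {matched, unmatched} x frequency
    trial_counts: pd.DataFrame   # equalised trial count per participant x frequency
    excluded: list[int]          # participants removed by Chauvenet
    anova: RmAnovaResult

    def matched_minus_unmatched(self) -> pd.Series:
        m = self.table.xs("matched", level="condition")
        u = self.table.xs("unmatched", level="condition")
        return (m - u).mean(axis=1)

    def to_dict(self) -> dict:
        return {
            "stage": "entrainment",
            "anova": self.anova.to_dict(),
            "excluded_participants": self.excluded,
            "mean_matched": self.table.xs("matched", level="condition").mean().to_dict(),
            "mean_unmatched": self.table.xs("unmatched", level="condition").mean().to_dict(),
            "trial_counts": self.trial_counts.to_dict(orient="index"),
        }


def induced_point_values(study: Study, participant: int, seed: int,
                         decimate: int = 12) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Matched and unmatched induced-amplitude point values for one
    participant, with equalised trial counts.

    For each rate f the induced response of a trial is the mean amplitude
    over the rate-specific active window minus the mean over its
    equal-duration baseline, in the band centred on f.  Matched draws the
    trials presented at f; unmatched draws an equal-size random subsample
    of all other trials, read in the same band and windows.
    """
    rng = np.random.default_rng(seed)
    trials = study.participant_trials(participant)
    keep = ~trials["rejected"].to_numpy()
    freqs = trials["frequency"].to_numpy()[keep]
    epochs = study.epochs[participant]
    tf = hilbert_tf(epochs, frequencies=PRESENTATION_BANDS, decimate=decimate)
    bounds = (float(tf.times[0]), float(tf.times[-1]))
    duty = study.truth.duty_cycle

    matched = np.empty(len(PRESENTATION_BANDS))
    unmatched = np.empty(len(PRESENTATION_BANDS))
    counts = np.empty(len(PRESENTATION_BANDS), dtype=int)
    for i, f in enumerate(PRESENTATION_BANDS):
        active, baseline = entrainment_windows(f, duty, epoch_bounds=bounds)
        induced = (window_mean_amplitude(tf, active, f)
                   - window_mean_amplitude(tf, baseline, f))[keep]
        is_f = freqs == f
        n_f = int(is_f.sum())
        pool = np.nonzero(~is_f)[0]
        if n_f == 0 or pool.size < n_f:
            raise ValueError(
                f"participant {participant}: cannot equalise trial counts at {f} Hz "
                f"({n_f} matched, {pool.size} available unmatched)")
        sample = rng.choice(pool, size=n_f, replace=False)
        matched[i] = induced[is_f].mean()
        unmatched[i] = induced[sample].mean()
        counts[i] = n_f
    return matched, unmatched, counts


def run_entrainment_stage(study: Study, seed: int = 0,
                          decimate: int = 12,
                          chauvenet_criterion: float = 0.5) -> EntrainmentResult:
    rng = np.random.default_rng(seed)
    participants = study.participants
    rows, count_rows = {}, {}
    for p in participants:
        m, u, c = induced_point_values(study, p, seed=int(rng.integers(0, 2**31)),
                                       decimate=decimate)
        rows[(p, "matched")] = m
        rows[(p, "unmatched")] = u
        count_rows[p] = c
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(PRESENTATION_FREQUENCIES))
    table.index = pd.MultiIndex.from_tuples(table.index,
                                            names=["participant", "condition"])
    counts = pd.DataFrame.from_dict(count_rows, orient="index",
                                    columns=list(PRESENTATION_FREQUENCIES))

    diffs = (table.xs("matched", level="condition")
             - table.xs("unmatched", level="condition")).mean(axis=1)
    include = chauvenet(diffs.to_numpy(), chauvenet_criterion)
    excluded = [int(p) for p, ok in zip(diffs.index, include) if not ok]
    if excluded:
        log.warning("entrainment stage: Chauvenet excluded participants %s", excluded)
    survivors = [p for p, ok in zip(diffs.index, include) if ok]
    cube = np.stack([
        np.stack([table.loc[(p, "matched")].to_numpy(),
                  table.loc[(p, "unmatched")].to_numpy()])
        for p in survivors])
    anova = rm_anova_2x12(cube)
    return EntrainmentResult(table=table, trial_counts=counts,
                             excluded=excluded, anova=anova)


# ---------------------------------------------------------------------------
# Stage 3: successful vs unsuccessful contrast

@dataclass
class SuccessContrastResult:
    amplitude_raw: ClusterResult
    amplitude_baselined: ClusterResult
    plv_difference: ClusterResult
    phase_angle: ClusterResult
    rayleigh: dict                  # per condition: {"z": map, "p": map}
    frequencies: np.ndarray
    times: np.ndarray
    trial_counts: pd.Series         # equal-n per participant
    dropped: list[int]

    def to_dict(self) -> dict:
        return {
            "stage": "success_contrast",
            "amplitude_raw": self.amplitude_raw.to_dict(),
            "amplitude_baselined": self.amplitude_baselined.to_dict(),
            "plv_difference": self.plv_difference.to_dict(),
            "phase_angle": self.phase_angle.to_dict(),
            "trial_counts": {str(k): int(v) for k, v in self.trial_counts.items()},
            "dropped_participants": self.dropped,
            "frequencies": self.frequencies.tolist(),
            "n_times": int(self.times.size),
        }


def equalise_success_sets(trials: pd.DataFrame, rng: np.random.Generator,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Row positions (within ``trials``) of the equal-n success/failure sets."""
    correct = trials["correct"].to_numpy(dtype=bool)
    pos = np.arange(len(trials))
    succ, fail = pos[correct], pos[~correct]
    n = min(succ.size, fail.size)
    if n == 0:
        raise ValueError("participant lacks trials in one outcome")
    if succ.size > n:
        succ = rng.choice(succ, size=n, replace=False)
    if fail.size > n:
        fail = rng.choice(fail, size=n, replace=False)
    return np.sort(succ), np.sort(fail)


def run_success_contrast_stage(study: Study, seed: int = 0,
                               frequencies: np.ndarray = FREQ_GRID,
                               decimate: int = 12,
                               n_permutations: int = 5000,
                               alpha_inclusion: float = 0.05,
                               connectivity: int = 8,
                               chauvenet_criterion: float | None = 0.5,
                               ) -> SuccessContrastResult:
    """Four cluster analyses contrasting successful vs unsuccessful counting
    on the pooled high-prevalence (10 and 14 Hz) trials."""
    frequencies = np.asarray(frequencies, dtype=float)
    rng = np.random.default_rng(seed)
    amp_s, amp_f, base_s, base_f = [], [], [], []
    plv_s, plv_f, ang_s, ang_f = [], [], [], []
    counts, dropped, used = {}, [], []
    times = None

    for p in study.participants:
        trials = study.participant_trials(p)
        sel = trials["frequency"].isin(HIGH_PREVALENCE_FREQUENCIES).to_numpy()
        sel &= ~trials["rejected"].to_numpy()
        sub = trials[sel]
        try:
            succ, fail = equalise_success_sets(
                sub, np.random.default_rng(int(rng.integers(0, 2**31))))
        except ValueError:
            log.warning("success contrast: participant %s has no trials in one "
                        "outcome; dropped", p)
            dropped.append(int(p))
            continue
        epochs = study.epochs[p]
        idx = np.nonzero(sel)[0]
        tf = hilbert_tf(
            type(epochs)(epochs.data[idx], fs=epochs.fs, t_start=epochs.t_start,
                         audio_offset=epochs.audio_offset),
            frequencies=frequencies, decimate=decimate)
        tf_base = apply_baseline(tf)
        times = tf.times
        for cond, rows in (("s", succ), ("f", fail)):
            amp = tf.amplitude[rows].mean(axis=0)
            base = tf_base.amplitude[rows].mean(axis=0)
            pl = plv(tf.phase[rows], axis=0)
            ang, _ = circ_mean(tf.phase[rows], axis=0)
            if cond == "s":
                amp_s.append(amp); base_s.append(base); plv_s.append(pl); ang_s.append(ang)
            else:
                amp_f.append(amp); base_f.append(base); plv_f.append(pl); ang_f.append(ang)
        counts[int(p)] = int(len(succ))
        used.append(int(p))

    if len(used) < 2:
        raise ValueError("success contrast needs at least 2 usable participants")

    def stack(lst):
        return np.stack(lst)

    seeds = rng.integers(0, 2**31, 4)
    kwargs = dict(n_permutations=n_permutations, alpha_inclusion=alpha_inclusion,
                  connectivity=connectivity)
    res_amp = cluster_permutation(stack(amp_s), stack(amp_f), "paired_t",
                                  seed=int(seeds[0]),
                                  chauvenet_criterion=chauvenet_criterion, **kwargs)
    res_base = cluster_permutation(stack(base_s), stack(base_f), "paired_t",
                                   seed=int(seeds[1]),
                                   chauvenet_criterion=chauvenet_criterion, **kwargs)
    res_plv = cluster_permutation(stack(plv_s), stack(plv_f), "plv_diff_t",
                                  seed=int(seeds[2]),
                                  chauvenet_criterion=chauvenet_criterion, **kwargs)
    res_phase = cluster_permutation(stack(ang_s), stack(ang_f), "watson_u2",
                                    seed=int(seeds[3]), **kwargs)

    rayleigh = {}
    for name, angles in (("successful", stack(ang_s)), ("unsuccessful", stack(ang_f))):
        z, pmap = rayleigh_map(angles, axis=0)
        rayleigh[name] = {"z": z, "p": pmap}

    return SuccessContrastResult(
        amplitude_raw=res_amp, amplitude_baselined=res_base,
        plv_difference=res_plv, phase_angle=res_phase, rayleigh=rayleigh,
        frequencies=frequencies, times=times,
        trial_counts=pd.Series(counts), dropped=dropped)
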