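"""Statistical engines: JZS Bayes factors, Chauvenet exclusion,
within-subject ANCOVA, balanced repeated-measures ANOVA, and the
max-cluster-mass permutation test.

The JZS Bayes factor follows the one-sample formulation of Rouder,
Speckman, Sun, Morey & Iverson (2009): a Cauchy prior with scale ``r``
on standardised effect size, integrated over the Jeffreys g prior by
adaptive quadrature on a transformed finite interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, ndimage, stats

from .circstats import U2_CRIT_05, u2_stat_map

__all__ = [
    "AncovaResult",
    "BFResult",
    "Cluster",
    "ClusterResult",
    "chauvenet",
    "chauvenet_mask",
    "cluster_permutation",
    "jzs_bf_from_t",
    "rm_anova_2x12",
    "within_subject_ancova",
]

DEFAULT_SCALE = float(np.sqrt(0.5))

#: Two-sample Watson U2 critical values (asymptotic), by inclusion alpha.
U2_CRITICAL = {0.10: 0.152, 0.05: U2_CRIT_05, 0.01: 0.268}


# ---------------------------------------------------------------------------
# JZS Bayes factor

@dataclass
class BFResult:
    t: float
    df: int
    n: int
    scale: float
    bf10: float

    def to_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "n": self.n,
                "scale": self.scale, "bf10": self.bf10}


def jzs_bf_from_t(t: float, n: int, scale: float = DEFAULT_SCALE) -> BFResult:
    """BF10 for a one-sample t statistic under the JZS prior.

    ``n`` is the effective sample size (nu = n - 1 degrees of freedom).
    The g integral is evaluated on g = u / (1 - u), u in (0, 1), with
    relative tolerance 1e-8; the alternative's marginal likelihood is
    normalised by the null's so only the ratio is integrated, which keeps
    the integrand well-scaled for large |t|.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if n < 2:
        raise ValueError("n must be at least 2")
    if scale <= 0:
        raise ValueError("scale must be positive")
    nu = n - 1
    t2 = float(t) ** 2

    def integrand(u: float) -> float:
        g = u / (1.0 - u)
        c = 1.0 + n * g * scale ** 2
        ratio = (1.0 + t2 / (c * nu)) / (1.0 + t2 / nu)
        dens = (2.0 * np.pi) ** -0.5 * g ** -1.5 * np.exp(-1.0 / (2.0 * g))
        return c ** -0.5 * ratio ** (-(nu + 1) / 2.0) * dens / (1.0 - u) ** 2

    bf10, _ = integrate.quad(integrand, 0.0, 1.0, epsrel=1e-8, limit=200)
    return BFResult(t=float(t), df=nu, n=int(n), scale=float(scale),
                    bf10=float(bf10))


# ---------------------------------------------------------------------------
# Chauvenet's criterion

def chauvenet(values, criterion: float = 0.5) -> np.ndarray:
    """Single-pass Chauvenet inclusion mask.

    A value is excluded when the expected number of observations at least
    as extreme under a fitted normal, ``N * P(|Z| >= |z|)``, falls below
    ``criterion``.  Zero-variance input excludes nothing.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("chauvenet needs at least 3 values")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    return chauvenet_mask(values.reshape(-1, 1), criterion)[:, 0]


def chauvenet_mask(values: np.ndarray, criterion: float = 0.5) -> np.ndarray:
    """Columnwise Chauvenet inclusion mask for (n, bins) arrays."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(values - mean) / sd
    expected = n * 2.0 * stats.norm.sf(z)
    mask = expected >= criterion
    mask[:, sd == 0] = True
    mask[np.isnan(z)] = True
    return mask


# ---------------------------------------------------------------------------
# Within-subject ANCOVA (Bland & Altman)

@dataclass
class AncovaResult:
    slope: float
    slope_se: float
    slope_t: float
    slope_f: float
    slope_df: tuple[int, int]
    slope_p: float
    r: float
    intercepts: np.ndarray
    intercept_mean: float
    intercept_se: float
    intercept_t: float
    intercept_df: int
    intercept_p: float
    intercept_bf: BFResult | None
    slope_bf: BFResult | None
    participant_f: float
    participant_df: tuple[int, int]
    participant_p: float
    participant_bf: None = None  # no JZS t-equivalent for an F(k-1, dfe) factor
    n_participants: int = 0
    n_obs: int = 0

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "slope_se": self.slope_se,
            "slope_t": self.slope_t, "slope_f": self.slope_f,
            "slope_df": list(self.slope_df), "slope_p": self.slope_p,
            "r": self.r,
            "intercepts": np.asarray(self.intercepts).tolist(),
            "intercept_mean": self.intercept_mean,
            "intercept_se": self.intercept_se,
            "intercept_t": self.intercept_t, "intercept_df": self.intercept_df,
            "intercept_p": self.intercept_p,
            "intercept_bf10": None if self.intercept_bf is None else self.intercept_bf.bf10,
            "slope_bf10": None if self.slope_bf is None else self.slope_bf.bf10,
            "participant_f": self.participant_f,
            "participant_df": list(self.participant_df),
            "participant_p": self.participant_p,
            "participant_bf10": None,
            "n_participants": self.n_participants, "n_obs": self.n_obs,
        }


def within_subject_ancova(x, y, participants, scale: float = DEFAULT_SCALE,
                          intercept_method: str = "per_participant",
                          ) -> AncovaResult:
    """Common-slope ANCOVA with participants partialled out as a factor.

    Fits ``y = a_participant + b * x``; the slope F has df
    (1, N_obs - N_participants - 1) and the within-subject correlation is
    ``sign(b) * sqrt(F / (F + df_error))``.  The intercept test is a
    one-sample t of the per-participant intercepts against zero
    (df = N_participants - 1); ``intercept_method="pooled"`` instead tests
    the grand intercept of a sum-coded model on the residual df.  JZS
    Bayes factors are attached to both slope and intercept tests using the
    number of participants as the effective sample size (the slope BF's
    effective N is not uniquely defined for this design; see docs).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    labels = np.asarray(participants).ravel()
    if not (x.size == y.size == labels.size):
        raise ValueError("x, y, participants must have equal length")
    uniq, idx = np.unique(labels, return_inverse=True)
    k = uniq.size
    n_obs = x.size
    counts = np.bincount(idx)
    if (counts < 3).any():
        raise ValueError("every participant needs at least 3 (x, y) pairs")

    X = np.zeros((n_obs, k + 1))
    X[np.arange(n_obs), idx] = 1.0
    X[:, -1] = x
    if np.linalg.matrix_rank(X) < k + 1:
        raise ValueError("rank-deficient design (constant x within participants?)")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_e = n_obs - k - 1
    mse = float(resid @ resid) / df_e
    xtx_inv = np.linalg.inv(X.T @ X)
    slope = float(beta[-1])
    slope_se = float(np.sqrt(mse * xtx_inv[-1, -1]))
    slope_t = slope / slope_se if slope_se > 0 else np.sign(slope) * np.inf
    slope_f = slope_t ** 2
    slope_p = float(stats.f.sf(slope_f, 1, df_e))
    r = float(np.sign(slope) * np.sqrt(slope_f / (slope_f + df_e))
              if np.isfinite(slope_f) else np.sign(slope))

    intercepts = beta[:k]
    if intercept_method == "pooled" or k == 1:
        # grand intercept of the equivalent sum-coded model, on residual df
        i_mean = float(intercepts.mean())
        comb = xtx_inv[:k, :k].sum() / k ** 2
        i_se = float(np.sqrt(mse * comb))
        i_t = i_mean / i_se
        i_df = df_e
        bf_n = k if k > 1 else n_obs
    elif intercept_method == "per_participant":
        i_mean = float(intercepts.mean())
        i_se = float(intercepts.std(ddof=1) / np.sqrt(k))
        i_t = i_mean / i_se if i_se > 0 else 0.0
        i_df = k - 1
        bf_n = k
    else:
        raise ValueError(f"unknown intercept_method {intercept_method!r}")
    i_p = float(2 * stats.t.sf(abs(i_t), i_df))

    # participant factor: full model vs slope-only model
    Xr = np.column_stack([np.ones(n_obs), x])
    beta_r, _, _, _ = np.linalg.lstsq(Xr, y, rcond=None)
    ss_r = float(np.sum((y - Xr @ beta_r) ** 2))
    ss_f = float(resid @ resid)
    if k > 1:
        part_f = ((ss_r - ss_f) / (k - 1)) / mse
        part_p = float(stats.f.sf(part_f, k - 1, df_e))
    else:
        part_f, part_p = 0.0, 1.0

    return AncovaResult(
        slope=slope, slope_se=slope_se, slope_t=float(slope_t),
        slope_f=float(slope_f), slope_df=(1, df_e), slope_p=slope_p, r=r,
        intercepts=intercepts, intercept_mean=i_mean, intercept_se=i_se,
        intercept_t=float(i_t), intercept_df=i_df, intercept_p=i_p,
        intercept_bf=(jzs_bf_from_t(i_t, max(bf_n, 2), scale)
                      if np.isfinite(i_t) else None),
        slope_bf=(jzs_bf_from_t(slope_t, max(k, 2), scale)
                  if np.isfinite(slope_t) and abs(slope_t) < 1e6 else None),
        participant_f=float(part_f), participant_df=(k - 1, df_e),
        participant_p=part_p, n_participants=k, n_obs=n_obs)


# ---------------------------------------------------------------------------
# Balanced two-way repeated-measures ANOVA (2 x 12 by default)

@dataclass
class RmAnovaResult:
    f_main: float
    df_main: tuple[int, int]
    p_main: float
    bf_main: BFResult
    f_freq: float
    df_freq: tuple[int, int]
    p_freq: float
    f_interaction: float
    df_interaction: tuple[int, int]
    p_interaction: float
    n_participants: int

    def to_dict(self) -> dict:
        return {
            "f_main": self.f_main, "df_main": list(self.df_main),
            "p_main": self.p_main, "bf10_main": self.bf_main.bf10,
            "f_freq": self.f_freq, "df_freq": list(self.df_freq),
            "p_freq": self.p_freq,
            "f_interaction": self.f_interaction,
            "df_interaction": list(self.df_interaction),
            "p_interaction": self.p_interaction,
            "n_participants": self.n_participants,
        }


def rm_anova_2x12(table: np.ndarray, scale: float = DEFAULT_SCALE) -> RmAnovaResult:
    """Two-way within-subject ANOVA on a complete (n, 2, k) table.

    Factor A (2 levels: matched vs unmatched) is the main question; factor
    B (k frequencies) and the A x B interaction probe frequency
    specificity.  The main-effect BF10 uses t = sqrt(F) with the number of
    participants as effective sample size.
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 3 or X.shape[1] != 2:
        raise ValueError("table must be (n_participants, 2, n_frequencies)")
    if not np.isfinite(X).all():
        raise ValueError("missing cells in the repeated-measures table")
    n, a, b = X.shape
    if n < 2:
        raise ValueError("need at least 2 participants")

    grand = X.mean()
    m_s = X.mean(axis=(1, 2))
    m_a = X.mean(axis=(0, 2))
    m_b = X.mean(axis=(0, 1))
    m_sa = X.mean(axis=2)
    m_sb = X.mean(axis=1)
    m_ab = X.mean(axis=0)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    f_a = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))

    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    f_b = (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1)))

    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    resid = (X - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :] - grand)
    ss_abs = np.sum(resid ** 2)
    df_ab = (a - 1) * (b - 1)
    df_abs = df_ab * (n - 1)
    f_ab = (ss_ab / df_ab) / (ss_abs / df_abs)

    sign = np.sign(m_a[0] - m_a[1]) or 1.0
    bf = jzs_bf_from_t(sign * np.sqrt(max(f_a, 0.0)), n, scale)
    return RmAnovaResult(
        f_main=float(f_a), df_main=(a - 1, n - 1),
        p_main=float(stats.f.sf(f_a, a - 1, n - 1)), bf_main=bf,
        f_freq=float(f_b), df_freq=(b - 1, (b - 1) * (n - 1)),
        p_freq=float(stats.f.sf(f_b, b - 1, (b - 1) * (n - 1))),
        f_interaction=float(f_ab), df_interaction=(df_ab, df_abs),
        p_interaction=float(stats.f.sf(f_ab, df_ab, df_abs)),
        n_participants=n)


# ---------------------------------------------------------------------------
# Max-cluster-mass permutation test

@dataclass
class Cluster:
    sign: int
    mass: float
    p_value: float
    bins: list[tuple[int, int]] = field(repr=False, default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def to_dict(self, with_bins: bool = True) -> dict:
        fi = [b[0] for b in self.bins]
        ti = [b[1] for b in self.bins]
        doc = {"sign": self.sign, "mass": self.mass, "p_value": self.p_value,
               "n_bins": self.n_bins,
               "freq_bins": [min(fi), max(fi)], "time_bins": [min(ti), max(ti)]}
        if with_bins:
            # run-length encode per frequency row: [fi, t_start, t_end]
            runs = []
            by_f: dict[int, list[int]] = {}
            for f, t in self.bins:
                by_f.setdefault(f, []).append(t)
            for f in sorted(by_f):
                ts = sorted(by_f[f])
                start = prev = ts[0]
                for t in ts[1:]:
                    if t != prev + 1:
                        runs.append([f, start, prev])
                        start = t
                    prev = t
                runs.append([f, start, prev])
            doc["bins_rle"] = runs
        return doc


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    stat_map: np.ndarray
    threshold_map: np.ndarray
    null_max: np.ndarray
    settings: dict

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]

    def to_dict(self) -> dict:
        # full bin inventories only where they matter; sub-threshold noise
        # clusters are counted, not inventoried
        return {
            "n_clusters_total": len(self.clusters),
            "clusters": [c.to_dict(with_bins=c.p_value <= 0.1)
                         for c in self.clusters if c.p_value <= 0.2],
            "null_max_quantiles": {
                str(q): float(np.quantile(self.null_max, q))
                for q in (0.5, 0.9, 0.95, 0.99)} if self.null_max.size else {},
            "settings": self.settings,
        }


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return np.ones((3, 3), dtype=bool)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError("connectivity must be 4 or 8")


def _extract_clusters(stat: np.ndarray, supra: np.ndarray,
                      structure: np.ndarray) -> list[tuple[float, np.ndarray]]:
    labels, n = ndimage.label(supra, structure=structure)
    out = []
    for lab in range(1, n + 1):
        member = labels == lab
        out.append((float(stat[member].sum()), member))
    return out


def _max_mass(stat: np.ndarray, thresh: np.ndarray, structure: np.ndarray,
              two_sided: bool) -> float:
    best = 0.0
    labels, n = ndimage.label(stat > thresh, structure=structure)
    if n:
        sums = ndimage.sum_labels(stat, labels, index=np.arange(1, n + 1))
        best = float(np.max(sums))
    if two_sided:
        labels, n = ndimage.label(stat < -thresh, structure=structure)
        if n:
            sums = ndimage.sum_labels(-stat, labels, index=np.arange(1, n + 1))
            best = max(best, float(np.max(sums)))
    return best


def _chauvenet_z_crit(n: int, criterion: float) -> float:
    """z above which a value fails Chauvenet: n * 2 * sf(z) < criterion."""
    return float(-stats.norm.ppf(criterion / (2.0 * n)))


def _t_maps(diff_flat: np.ndarray, signs: np.ndarray,
            z_crit: float | None) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin one-sample t maps for a batch of sign assignments.

    When ``z_crit`` is given, Chauvenet exclusion is recomputed for every
    sign assignment (via the equivalent normal-score threshold), so the
    statistic is a pure function of the permuted data and the permutation
    test stays exact.  Returns (t, n_included), each (P, B).
    """
    n = diff_flat.shape[0]
    if z_crit is None:
        n_bin = np.full((signs.shape[0], diff_flat.shape[1]), n)
        ssq = np.sum(diff_flat ** 2, axis=0)
        mean = (signs @ diff_flat) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            var = np.maximum((ssq - n * mean ** 2) / (n - 1), 0.0)
            t = mean / np.sqrt(var / n)
        return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0), n_bin

    X = signs[:, :, None] * diff_flat[None, :, :]          # (P, n, B)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    mask = np.abs(X - mu) <= z_crit * sd
    mask |= (sd == 0)
    n_bin = mask.sum(axis=1)
    s1 = np.sum(X, axis=1, where=mask)
    s2 = np.sum(X * X, axis=1, where=mask)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = s1 / n_bin
        var = np.maximum((s2 - n_bin * mean ** 2) / (n_bin - 1), 0.0)
        t = mean / np.sqrt(var / n_bin)
    t = np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)
    t[n_bin < 2] = 0.0
    return t, n_bin


def cluster_permutation(a_maps: np.ndarray, b_maps: np.ndarray | None = None,
                        statistic: str = "paired_t", n_permutations: int = 5000,
                        alpha_inclusion: float = 0.05, connectivity: int = 8,
                        seed: int = 0, chauvenet_criterion: float | None = 0.5,
                        ) -> ClusterResult:
    """Family-wise corrected time-frequency clusters via max cluster mass.

    ``a_maps``/``b_maps`` are (n_participants, n_freq, n_time) paired
    condition maps (``b_maps=None`` treats ``a_maps`` as paired
    differences).  ``statistic``:

    * ``"paired_t"`` / ``"plv_diff_t"`` - per-bin one-sample t on the
      differences, with optional per-bin Chauvenet exclusion (computed once
      on the observed data), two-sided threshold at ``alpha_inclusion``,
      and a sign-flip permutation null within participants;
    * ``"watson_u2"`` - per-bin two-sample Watson U2 on the two sets of
      angles (typically participant-mean phase angles), thresholded at the
      asymptotic critical value, with a condition-label-swap null.

    Cluster mass is the summed statistic over an 8-way connected
    supra-threshold component; each cluster's p is
    ``(1 + #{null max mass >= observed}) / (n_permutations + 1)``.
    """
    a_maps = np.asarray(a_maps, dtype=float)
    if b_maps is not None:
        b_maps = np.asarray(b_maps, dtype=float)
        if b_maps.shape != a_maps.shape:
            raise ValueError("condition maps must share the participant/frequency/time grid")
    if a_maps.ndim != 3:
        raise ValueError("maps must be (n_participants, n_freq, n_time)")
    n, nf, nt = a_maps.shape
    B = nf * nt
    structure = _structure(connectivity)
    rng = np.random.default_rng(seed)
    settings = {"statistic": statistic, "n_permutations": n_permutations,
                "alpha_inclusion": alpha_inclusion, "connectivity": connectivity,
                "seed": seed, "chauvenet_criterion": chauvenet_criterion,
                "n_participants": n, "grid": [nf, nt]}

    if statistic in ("paired_t", "plv_diff_t"):
        diffs = a_maps - b_maps if b_maps is not None else a_maps
        flat = diffs.reshape(n, B)
        z_crit = (None if chauvenet_criterion is None
                  else _chauvenet_z_crit(n, chauvenet_criterion))
        # critical t by included count (df = count - 1)
        tcrit_by_n = np.full(n + 1, np.inf)
        counts = np.arange(2, n + 1)
        tcrit_by_n[counts] = stats.t.ppf(1 - alpha_inclusion / 2, counts - 1)

        t_obs, n_obs_bin = _t_maps(flat, np.ones((1, n)), z_crit)
        stat_map = t_obs[0].reshape(nf, nt)
        thresh_map = tcrit_by_n[n_obs_bin[0]].reshape(nf, nt)

        clusters: list[Cluster] = []
        pieces = ([(1, m, mem) for m, mem in
                   _extract_clusters(stat_map, stat_map > thresh_map, structure)]
                  + [(-1, -m, mem) for m, mem in
                     _extract_clusters(-stat_map, stat_map < -thresh_map, structure)])

        null_max = np.zeros(n_permutations)
        per_perm = n * B if z_crit is not None else B
        chunk = max(1, min(n_permutations, 40_000_000 // max(per_perm, 1)))
        done = 0
        while done < n_permutations:
            p = min(chunk, n_permutations - done)
            signs = rng.choice([-1.0, 1.0], size=(p, n))
            t_perm, n_perm_bin = _t_maps(flat, signs, z_crit)
            for j in range(p):
                thr = tcrit_by_n[n_perm_bin[j]].reshape(nf, nt)
                null_max[done + j] = _max_mass(
                    t_perm[j].reshape(nf, nt), thr, structure, True)
            done += p

        for sign, mass, member in pieces:
            p_val = float((1 + np.sum(null_max >= abs(mass))) / (n_permutations + 1))
            fi, ti = np.nonzero(member)
            clusters.append(Cluster(sign=sign, mass=float(mass), p_value=p_val,
                                    bins=list(zip(fi.tolist(), ti.tolist()))))
        clusters.sort(key=lambda c: c.p_value)
        return ClusterResult(clusters, stat_map, thresh_map, null_max, settings)

    if statistic == "watson_u2":
        if b_maps is None:
            raise ValueError("watson_u2 needs both condition maps")
        crit = U2_CRITICAL.get(round(alpha_inclusion, 4))
        if crit is None:
            raise ValueError(f"no U2 critical value tabled for alpha={alpha_inclusion}")
        A = a_maps.reshape(n, B)
        Bb = b_maps.reshape(n, B)
        u_obs = u2_stat_map(A, Bb).reshape(nf, nt)
        thresh_map = np.full_like(u_obs, crit)

        null_max = np.zeros(n_permutations)
        for p in range(n_permutations):
            swap = rng.random(n) < 0.5
            Ap = np.where(swap[:, None], Bb, A)
            Bp = np.where(swap[:, None], A, Bb)
            u_perm = u2_stat_map(Ap, Bp).reshape(nf, nt)
            null_max[p] = _max_mass(u_perm, thresh_map, structure, False)

        clusters = []
        for mass, member in _extract_clusters(u_obs, u_obs > thresh_map, structure):
            p_val = float((1 + np.sum(null_max >= mass)) / (n_permutations + 1))
            fi, ti = np.nonzero(member)
            clusters.append(Cluster(sign=1, mass=mass, p_value=p_val,
                                    bins=list(zip(fi.tolist(), ti.tolist()))))
        clusters.sort(key=lambda c: c.p_value)
        return ClusterResult(clusters, u_obs, thresh_map, null_max, settings)

    raise ValueError(f"unknown statistic {statistic!r}")
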