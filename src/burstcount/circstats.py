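"""Circular statistics kernels for the success-contrast analyses.

Implements the circular mean and resultant length, the across-trial
phase-locking value, the Rayleigh test of uniformity (Zar's p
approximation), the parametric Watson-Williams multi-sample test with its
concentration/homogeneity diagnostics, and the nonparametric two-sample
Watson U-squared test with a seeded permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CircTestResult",
    "circ_mean",
    "plv",
    "rayleigh_test",
    "u2_stat",
    "watson_u2",
    "watson_williams",
]

#: Asymptotic 5% critical value of the two-sample Watson U2 statistic.
U2_CRIT_05 = 0.1869


@dataclass
class CircTestResult:
    statistic: float
    p_value: float
    mean_angle: float
    resultant_length: float
    test: str
    warning: str | None = None

    def to_dict(self) -> dict:
        return {
            "test": self.test, "statistic": float(self.statistic),
            "p_value": float(self.p_value), "mean_angle": float(self.mean_angle),
            "resultant_length": float(self.resultant_length),
            "warning": self.warning,
        }


def _wrap(angles: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(angles, dtype=float), 2 * np.pi)


def circ_mean(angles, axis: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Mean angle and resultant length of the mean unit vector.

    The mean angle is NaN-flagged when the resultant length is (numerically)
    zero, e.g. for antipodal pairs.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("circ_mean needs at least one angle")
    z = np.mean(np.exp(1j * angles), axis=axis)
    r = np.abs(z)
    mean = np.where(r > 1e-12, np.angle(z), np.nan)
    return mean, r


def plv(phases, axis: int = 0) -> np.ndarray:
    """Phase-locking value across trials: |mean of unit phasors|.

    1 for perfectly aligned phases, approaching 0 as consistency is lost
    (expected value ~ sqrt(pi / (4 N)) under uniformity).
    """
    phases = np.asarray(phases, dtype=float)
    if phases.shape[axis] == 0:
        raise ValueError("plv needs at least one trial")
    return np.abs(np.mean(np.exp(1j * phases), axis=axis))


def rayleigh_test(angles) -> CircTestResult:
    """Rayleigh test of circular uniformity (H0) vs unimodal concentration.

    z = n * rbar**2 with Zar's approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - (n rbar)^2)) - (1 + 2n)).
    """
    angles = np.asarray(angles, dtype=float).ravel()
    n = angles.size
    mean, rbar = circ_mean(angles)
    z = n * rbar ** 2
    R = n * rbar
    p = float(np.exp(np.sqrt(1 + 4 * n + 4 * (n ** 2 - R ** 2)) - (1 + 2 * n)))
    p = min(p, 1.0)
    warning = "n < 4: Rayleigh approximation unreliable" if n < 4 else None
    return CircTestResult(statistic=float(z), p_value=p,
                          mean_angle=float(mean), resultant_length=float(rbar),
                          test="rayleigh", warning=warning)


def rayleigh_map(angles: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Rayleigh z and p along ``axis`` (for time-frequency maps)."""
    angles = np.asarray(angles, dtype=float)
    n = angles.shape[axis]
    _, rbar = circ_mean(angles, axis=axis)
    z = n * rbar ** 2
    R = n * rbar
    p = np.minimum(np.exp(np.sqrt(1 + 4 * n + 4 * (n ** 2 - R ** 2)) - (1 + 2 * n)), 1.0)
    return z, p


def _kappa_from_rbar(rbar: float) -> float:
    """Maximum-likelihood-ish concentration estimate (Fisher/Zar)."""
    if rbar < 0.53:
        return 2 * rbar + rbar ** 3 + 5 * rbar ** 5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar ** 3 - 4 * rbar ** 2 + 3 * rbar)


def watson_williams(*groups) -> CircTestResult:
    """Watson-Williams test for equal mean directions of >= 2 samples.

    Assumes adequate, comparable concentrations; when the pooled
    concentration is low (rbar < 0.45) the result carries a homogeneity
    warning recommending the nonparametric U2 alternative.
    """
    from scipy import stats as sstats

    if len(groups) < 2:
        raise ValueError("watson_williams needs at least two groups")
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    sizes = np.array([g.size for g in groups])
    if (sizes < 5).any():
        raise ValueError("each group needs n >= 5")
    k = len(groups)
    N = int(sizes.sum())
    Rs = np.array([g.size * circ_mean(g)[1] for g in groups])
    pooled = np.concatenate(groups)
    mean_all, rbar_all = circ_mean(pooled)
    R = N * rbar_all

    rbar_w = float(Rs.sum() / N)
    kappa = _kappa_from_rbar(rbar_w)
    correction = 1 + 3 / (8 * kappa) if kappa > 0 else 1.0
    denom = N - Rs.sum()
    if denom <= 0:
        f = 0.0 if np.isclose(Rs.sum(), R) else np.inf
    else:
        f = correction * ((Rs.sum() - R) * (N - k)) / (denom * (k - 1))
    f = max(float(f), 0.0)
    p = float(sstats.f.sf(f, k - 1, N - k))
    warning = None
    if rbar_w < 0.45:
        warning = ("low concentration (rbar < 0.45): Watson-Williams "
                   "assumptions violated; use watson_u2")
    return CircTestResult(statistic=f, p_value=p, mean_angle=float(mean_all),
                          resultant_length=rbar_w, test="watson_williams",
                          warning=warning)


def u2_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Watson U2 from the ranked circular CDF difference."""
    return float(u2_stat_map(np.asarray(a, float).reshape(-1, 1),
                             np.asarray(b, float).reshape(-1, 1))[0])


def u2_stat_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised U2 over the trailing axes: a is (n, ...), b is (m, ...).

    U2 = nm/N^2 * [sum(d^2) - (sum d)^2 / N] with d the difference of the
    two empirical CDFs at the pooled sorted angles; rotation-invariant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.shape[0], b.shape[0]
    N = n + m
    pooled = np.concatenate([a, b], axis=0)
    is_a = np.zeros(pooled.shape, dtype=float)
    is_a[:n] = 1.0
    order = np.argsort(pooled, axis=0, kind="stable")
    a_sorted = np.take_along_axis(is_a, order, axis=0)
    ca = np.cumsum(a_sorted, axis=0) / n
    cb = np.cumsum(1.0 - a_sorted, axis=0) / m
    d = ca - cb
    return (n * m / N ** 2) * (np.sum(d ** 2, axis=0) - np.sum(d, axis=0) ** 2 / N)


def watson_u2(angles_a, angles_b, n_permutations: int = 5000,
              seed: int = 0, paired: bool | None = None) -> CircTestResult:
    """Nonparametric Watson U2 with a permutation null.

    ``paired=True`` (the default when sample sizes match) swaps the two
    condition values within each unit - the pool-and-resplit of condition
    labels within participant used at the group level.  Otherwise labels
    are reshuffled over the pooled sample.  p uses the +1 correction:
    p = (1 + #{permuted U2 >= observed}) / (n_permutations + 1).
    """
    a = _wrap(np.asarray(angles_a, dtype=float).ravel())
    b = _wrap(np.asarray(angles_b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if paired is None:
        paired = a.size == b.size
    if paired and a.size != b.size:
        raise ValueError("paired permutation requires equal sample sizes")
    rng = np.random.default_rng(seed)
    observed = u2_stat(a, b)

    if paired:
        swap = rng.random((n_permutations, a.size)) < 0.5
        A = np.where(swap, b[None, :], a[None, :]).T  # (n, P)
        B = np.where(swap, a[None, :], b[None, :]).T
        null = u2_stat_map(A, B)
    else:
        pooled = np.concatenate([a, b])
        idx = np.argsort(rng.random((n_permutations, pooled.size)), axis=1)
        shuffled = pooled[idx]  # (P, N)
        null = u2_stat_map(shuffled[:, :a.size].T, shuffled[:, a.size:].T)

    p = float((1 + np.sum(null >= observed - 1e-15)) / (n_permutations + 1))
    mean_all, rbar_all = circ_mean(np.concatenate([a, b]))
    return CircTestResult(statistic=observed, p_value=p, mean_angle=float(mean_all),
                          resultant_length=float(rbar_all), test="watson_u2")
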