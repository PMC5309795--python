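"""Shared statistical machinery: cluster-mass permutation tests, percentile
nulls, label-permutation z-scores and Fisher's z transform.

The cluster test follows the permutation-t construction: condition labels are
shuffled at the trial level, the per-timepoint difference of condition means
is recomputed for every shuffle, each difference series (observed and null) is
standardized against the null ensemble, contiguous supra-threshold runs are
summed into cluster masses, and the observed masses are compared with the
distribution of the maximal null cluster mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class Cluster:
    start: int
    end: int            # inclusive sample index
    mass: float
    corrected_p: float

    @property
    def sign(self) -> int:
        return 1 if self.mass > 0 else -1


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    null_masses: np.ndarray
    t_obs: np.ndarray
    cluster_forming_alpha: float = 0.05
    n_perm: int = 1000
    extra: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.corrected_p < alpha]


def _find_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, end) inclusive."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0])
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask) - 1)
    return list(zip(starts, ends))


def _cluster_masses(t: np.ndarray, thr: float) -> list[tuple[int, int, float]]:
    """Two-tailed clusters: positive and negative runs, mass = sum of t."""
    out = []
    for sign in (1, -1):
        for s, e in _find_runs(sign * t > thr):
            out.append((s, e, float(t[s:e + 1].sum())))
    return sorted(out, key=lambda c: c[0])


def cluster_permutation_test(trials_a: np.ndarray, trials_b: np.ndarray,
                             n_perm: int = 1000, alpha: float = 0.05,
                             seed: int | np.random.Generator = 0) -> ClusterTestResult:
    """Cluster-mass permutation test between two sets of trial time series.

    ``trials_a`` / ``trials_b``: (n_trials, n_samples).  Labels are shuffled
    ``n_perm`` times; per-timepoint permutation-t scores are the observed (or
    null) mean difference standardized by the null ensemble mean and SD.
    Zero-variance timepoints are excluded from cluster formation.
    """
    rng = np.random.default_rng(seed)
    a = np.atleast_2d(np.asarray(trials_a, dtype=float))
    b = np.atleast_2d(np.asarray(trials_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("conditions must share the sample grid")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 trials per condition")
    na = a.shape[0]
    pooled = np.vstack([a, b])
    n_tot = pooled.shape[0]
    obs = a.mean(axis=0) - b.mean(axis=0)

    null = np.empty((n_perm, a.shape[1]))
    for p in range(n_perm):
        perm = rng.permutation(n_tot)
        null[p] = pooled[perm[:na]].mean(axis=0) - pooled[perm[na:]].mean(axis=0)

    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=0)
    ok = sd > 0
    t_obs = np.zeros_like(obs)
    t_obs[ok] = (obs[ok] - mu[ok]) / sd[ok]
    t_null = np.zeros_like(null)
    t_null[:, ok] = (null[:, ok] - mu[ok]) / sd[ok]

    thr = float(stats.norm.ppf(1 - alpha / 2))
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        masses = _cluster_masses(t_null[p], thr)
        if masses:
            null_max[p] = max(abs(m) for *_, m in masses)

    clusters = []
    for s, e, m in _cluster_masses(t_obs, thr):
        cp = (1 + np.sum(null_max >= abs(m))) / (n_perm + 1)
        clusters.append(Cluster(s, e, m, float(cp)))
    return ClusterTestResult(clusters, null_max, t_obs, alpha, n_perm)


def onset_offset_from_clusters(result: ClusterTestResult, alpha: float = 0.05,
                               min_sample: int = 0,
                               sign: int = 0) -> tuple[int, int] | None:
    """First and last sample inside any corrected-significant cluster.

    ``min_sample`` restricts the search to samples at or after it (e.g. the
    stimulus-onset sample, so tonic pre-stimulus differences induced by
    within-trial normalization are not read as an evoked onset).  ``sign``
    +1/-1 keeps only positive/negative clusters (e.g. +1 for the onset of an
    'aversive greater than neutral' response); 0 keeps both.
    """
    sig = [c for c in result.significant(alpha)
           if c.end >= min_sample and (sign == 0 or c.sign == sign)]
    if not sig:
        return None
    return (min(max(c.start, min_sample) for c in sig),
            max(c.end for c in sig))


def percentile_null(statistic_fn, permute_fn, q: float, n_perm: int,
                    seed: int | np.random.Generator = 0) -> float:
    """q-th percentile of ``statistic_fn(permute_fn(rng))`` over n_perm draws.

    ``permute_fn(rng)`` produces one permuted replicate of the data;
    percentiles use linear interpolation.
    """
    if not 0 < q < 100:
        raise ValueError("q must be in (0, 100)")
    if q >= 99 and n_perm < 100:
        raise ValueError("need n_perm >= 100 for q >= 99")
    rng = np.random.default_rng(seed)
    vals = np.array([statistic_fn(permute_fn(rng)) for _ in range(n_perm)])
    return float(np.percentile(vals, q))


def fisher_z(rho: np.ndarray | float) -> np.ndarray | float:
    """Fisher's z transform, arctanh(rho); |rho| >= 1 is clipped with warning."""
    r = np.asarray(rho, dtype=float)
    if np.any(np.abs(r) >= 1):
        warnings.warn("|rho| >= 1 clipped to 1 - 1e-12 before Fisher z")
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    out = np.arctanh(r)
    return float(out) if np.isscalar(rho) else out


def z_difference(rho1, rho2):
    """Delta rho_z = z(rho1) - z(rho2)."""
    return fisher_z(rho1) - fisher_z(rho2)


__all__ = [
    "Cluster",
    "ClusterTestResult",
    "cluster_permutation_test",
    "onset_offset_from_clusters",
    "percentile_null",
    "fisher_z",
    "z_difference",
]
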