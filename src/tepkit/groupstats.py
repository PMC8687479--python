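"""Resilience classification and group-level statistics on evoked time-series.

The centrepiece is a nonparametric permutation test with cluster correction:
the observed statistic is the pointwise difference of group means over the
response window; pointwise p-values come from the permutation distribution of
that difference; contiguous significant samples form clusters, and a cluster
survives if both its size (timepoint count) and its magnitude (summed
absolute mean difference, "cluster mass") exceed the 95th percentile of the
corresponding permutation null distributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .io import window_indices

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# questionnaire scoring
# ---------------------------------------------------------------------------

@dataclass
class ResilienceLabel:
    subject_id: str
    label: str  # "resilient" | "vulnerable"
    n_pandemic_timepoints: int


def classify_resilience(phq_pre: int, phq_pandemic: list[int],
                        subject_id: str = "") -> ResilienceLabel:
    """Resilient iff every pandemic PHQ-4 total is <= the pre-pandemic total.

    A single pandemic score above the pre-pandemic baseline, at any
    timepoint, classifies the subject as vulnerable.
    """
    if not 0 <= phq_pre <= 12:
        raise ValueError(f"phq_pre={phq_pre} outside 0-12")
    if not phq_pandemic:
        raise ValueError("phq_pandemic must contain at least one score")
    if not 1 <= len(phq_pandemic) <= 3:
        raise ValueError("phq_pandemic must contain 1-3 scores")
    for p in phq_pandemic:
        if not 0 <= p <= 12:
            raise ValueError(f"pandemic score {p} outside 0-12")
    label = "resilient" if all(p <= phq_pre for p in phq_pandemic) else "vulnerable"
    return ResilienceLabel(subject_id=subject_id, label=label,
                           n_pandemic_timepoints=len(phq_pandemic))


def mean_pandemic_score(phq_pandemic: list[int]) -> float:
    """Arithmetic mean of the completed pandemic PHQ-4 totals."""
    if not phq_pandemic:
        raise ValueError("phq_pandemic must contain at least one score")
    return float(np.mean(phq_pandemic))


def screen_positive(subscale_score: int) -> bool:
    """PHQ-2/GAD-2 screening: a subscale score of 3 or greater is positive."""
    if not (isinstance(subscale_score, (int, np.integer)) and 0 <= subscale_score <= 6):
        raise ValueError(f"subscale score {subscale_score!r} outside 0-6")
    return subscale_score >= 3


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p.

    p-value from the t approximation on n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# cluster permutation test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cluster:
    start_ms: float
    end_ms: float
    size: int          # number of contiguous significant timepoints
    magnitude: float   # sum of |mean difference| over the cluster


@dataclass
class ClusterTestResult:
    times_ms: np.ndarray
    diff: np.ndarray
    pointwise_p: np.ndarray
    clusters: list[Cluster]
    surviving: list[Cluster]
    null_max_size: np.ndarray
    null_max_magnitude: np.ndarray
    n_perm: int
    seed: int | None
    alpha: float
    percentile: float
    null_mode: str

    def to_dict(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "seed": self.seed,
            "alpha": self.alpha,
            "percentile": self.percentile,
            "null_mode": self.null_mode,
            "times_ms": self.times_ms.tolist(),
            "diff": self.diff.tolist(),
            "pointwise_p": self.pointwise_p.tolist(),
            "clusters": [vars(c) for c in self.clusters],
            "surviving": [vars(c) for c in self.surviving],
            "null_size_threshold": float(np.percentile(self.null_max_size, self.percentile))
            if len(self.null_max_size) else None,
            "null_magnitude_threshold": float(
                np.percentile(self.null_max_magnitude, self.percentile))
            if len(self.null_max_magnitude) else None,
        }


def _find_runs(sig: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop inclusive."""
    if not sig.any():
        return []
    padded = np.concatenate(([False], sig, [False]))
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0] - 1
    return list(zip(starts, stops))


def _clusters_from_p(p: np.ndarray, diff: np.ndarray, times: np.ndarray,
                     alpha: float) -> list[Cluster]:
    out = []
    for a, b in _find_runs(p < alpha):
        out.append(Cluster(
            start_ms=float(times[a]), end_ms=float(times[b]),
            size=int(b - a + 1),
            magnitude=float(np.abs(diff[a:b + 1]).sum()),
        ))
    return out


def _stack_window(group, window):
    mats = []
    times_ref = None
    for rs in group:
        t = rs.times
        if times_ref is None:
            times_ref = t
        elif len(t) != len(times_ref) or not np.allclose(t, times_ref):
            raise ValueError("all series must share the same time axis")
        mats.append(rs.values)
    idx = window_indices(times_ref, *window)
    return np.stack(mats)[:, idx], times_ref[idx]


def cluster_permutation_test(
    group_a,
    group_b,
    window: tuple[float, float] = (15.0, 400.0),
    n_perm: int = 1000,
    alpha: float = 0.05,
    percentile: float = 95.0,
    null_mode: str = "max_per_perm",
    seed: int | None = None,
    exact: bool = False,
) -> ClusterTestResult:
    """Two-sided permutation test of pointwise group mean differences with
    cluster correction on both cluster size and cluster magnitude.

    Parameters
    ----------
    group_a, group_b : lists of ResponseSeries (or any object with ``.values``
        and ``.times``), one per subject; equal time axes required.
    null_mode : "max_per_perm" records, per permutation, the maximum cluster
        size and maximum cluster magnitude (the standard FWER-controlling max
        statistic).  "pooled" pools every cluster discovered across all
        permutations into the null distributions.
    exact : enumerate all label assignments instead of Monte-Carlo sampling
        (feasible only for small groups); ``n_perm`` is then ignored.

    A cluster survives iff its size exceeds the ``percentile``-th percentile
    of the null sizes AND its magnitude exceeds the same percentile of the
    null magnitudes.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if null_mode not in ("max_per_perm", "pooled"):
        raise ValueError(f"unknown null_mode {null_mode!r}")
    if not exact and n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low; p-values will be coarse")

    xa, times = _stack_window(group_a, window)
    xb, _ = _stack_window(group_b, window)
    if xa.shape[1] != xb.shape[1]:
        raise ValueError("groups have mismatched time axes")
    na, nb = len(xa), len(xb)
    pooled = np.vstack([xa, xb])  # (na+nb, T)
    n_tot = na + nb

    d_obs = xa.mean(axis=0) - xb.mean(axis=0)

    if exact:
        assignments = np.array(
            [list(c) for c in combinations(range(n_tot), na)], dtype=int
        )
    else:
        rng = np.random.default_rng(seed)
        assignments = np.empty((n_perm, na), dtype=int)
        for j in range(n_perm):
            assignments[j] = rng.permutation(n_tot)[:na]
    B = len(assignments)

    # permutation difference matrix D: (B, T) via group-membership algebra
    sel = np.zeros((B, n_tot))
    rows = np.repeat(np.arange(B), na)
    sel[rows, assignments.ravel()] = 1.0
    total = pooled.sum(axis=0)  # (T,)
    sum_a = sel @ pooled
    D = sum_a / na - (total - sum_a) / nb

    abs_D = np.abs(D)
    abs_obs = np.abs(d_obs)
    if exact:
        # observed assignment is a member of the enumerated ensemble
        p_obs = (abs_D >= abs_obs - 1e-12).sum(axis=0) / B
    else:
        p_obs = ((abs_D >= abs_obs - 1e-12).sum(axis=0) + 1.0) / (B + 1.0)

    clusters = _clusters_from_p(p_obs, d_obs, times, alpha)

    # null clustering: each permutation's pointwise p against the ensemble
    # (rank of |D_j(t)| among all |D_k(t)|, larger |D| -> smaller p)
    order_ranks = stats.rankdata(abs_D, axis=0, method="average")
    p_perm = (B - order_ranks + 1.0) / B  # (B, T)
    null_sizes: list[float] = []
    null_mags: list[float] = []
    for j in range(B):
        cl = _clusters_from_p(p_perm[j], D[j], times, alpha)
        if null_mode == "max_per_perm":
            null_sizes.append(max((c.size for c in cl), default=0))
            null_mags.append(max((c.magnitude for c in cl), default=0.0))
        else:
            null_sizes.extend(c.size for c in cl)
            null_mags.extend(c.magnitude for c in cl)

    null_sizes_arr = np.asarray(null_sizes, dtype=float)
    null_mags_arr = np.asarray(null_mags, dtype=float)
    if len(null_sizes_arr):
        size_thr = np.percentile(null_sizes_arr, percentile)
        mag_thr = np.percentile(null_mags_arr, percentile)
        surviving = [c for c in clusters
                     if c.size > size_thr and c.magnitude > mag_thr]
    else:
        surviving = list(clusters)

    log.debug("cluster test: n=%d vs %d, %d clusters, %d surviving",
              na, nb, len(clusters), len(surviving))
    return ClusterTestResult(
        times_ms=times, diff=d_obs, pointwise_p=p_obs,
        clusters=clusters, surviving=surviving,
        null_max_size=null_sizes_arr, null_max_magnitude=null_mags_arr,
        n_perm=B, seed=seed, alpha=alpha, percentile=percentile,
        null_mode=null_mode,
    )
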