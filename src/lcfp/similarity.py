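"""Similarity quantification between fingerprints.

The similarity index expresses a pair's RMSE distance d1 relative to the
expected distance d0 between unrelated subjects scanned with the same
protocol: similarity = 100%·(1 − d1/d0).  100% means identical fingerprints,
0% means the pair differs as much as unrelated subjects do (negative values
are possible).  This module also provides the longitudinal trend analysis
(Mann-Kendall test plus least-squares slope per 100 days) and the kinship
group comparisons (Kruskal-Wallis omnibus, Scheffé post-hoc on ranks, and
label-permutation tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .identify import DistanceMatrix, partition_differences

__all__ = [
    "SimilarityRecord",
    "TrendResult",
    "GroupTestResult",
    "expected_unrelated_distance",
    "similarity_index",
    "mann_kendall",
    "similarity_slope",
    "trend_analysis",
    "kruskal_wallis",
    "scheffe_posthoc",
    "permutation_test",
]

KIN_RELATIONS = ("MZ", "DZ", "SIB")


@dataclass(frozen=True)
class SimilarityRecord:
    """Similarity of one scan pair relative to the unrelated-pair baseline."""

    pair: tuple[str, str]
    d1: float
    d0: float

    @property
    def similarity(self) -> float:
        return similarity_index(self.d1, self.d0)


@dataclass(frozen=True)
class TrendResult:
    """Longitudinal trend of similarity: Mann-Kendall S/p and OLS slope."""

    S: int
    p_value: float
    slope_per_100_days: float


@dataclass
class GroupTestResult:
    """Kruskal-Wallis omnibus with Scheffé and permutation follow-ups."""

    chi2: float
    df: int
    p_value: float
    posthoc: dict
    perm_p: dict
    n_perm: int


def _kin_pair_mask(labels: pd.DataFrame, kinship: pd.DataFrame, iu: np.ndarray, ju: np.ndarray) -> np.ndarray:
    """True where a between-subject pair is genetically related (same family)."""
    fam = kinship.set_index("subject_id")["family_id"]
    fam_i = labels.subject_id.map(fam).to_numpy()
    related = (fam_i[iu] == fam_i[ju]) & pd.notna(fam_i[iu]) & pd.notna(fam_i[ju])
    return np.asarray(related, dtype=bool)


def expected_unrelated_distance(dm: DistanceMatrix, kinship: Optional[pd.DataFrame] = None) -> float:
    """Mean distance over unrelated-subject pairs (the d0 baseline).

    Within-subject pairs are always excluded; when a kinship table
    (subject_id, family_id, relation) is given, pairs from the same family
    are excluded as well.
    """
    subj = dm.labels.subject_id.to_numpy()
    iu, ju = np.triu_indices(len(dm), k=1)
    qualify = subj[iu] != subj[ju]
    if kinship is not None:
        qualify &= ~_kin_pair_mask(dm.labels, kinship, iu, ju)
    if not np.any(qualify):
        raise ValueError("no qualifying unrelated-subject pairs")
    return float(dm.values[iu[qualify], ju[qualify]].mean())


def similarity_index(d1: float, d0: float) -> float:
    """100%·(1 − d1/d0); 100 iff the two fingerprints are identical."""
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    if d1 < 0:
        raise ValueError("d1 must be non-negative")
    return 100.0 * (1.0 - d1 / d0)


def _mk_exact_p(s_obs: int, n: int) -> float:
    """Two-sided exact p-value of the Mann-Kendall S for tie-free data.

    The null distribution of the number of inversions of a random
    permutation is built by polynomial convolution; S = C(n,2) − 2·inv.
    """
    counts = np.array([1.0])
    for k in range(1, n):
        counts = np.convolve(counts, np.ones(k + 1))
    total = counts.sum()
    inv = np.arange(counts.size)
    s_all = n * (n - 1) // 2 - 2 * inv
    p_one = counts[np.abs(s_all) >= abs(s_obs)].sum() / total
    return float(min(1.0, p_one))


def mann_kendall(xs: Sequence[tuple[float, float]], exact_max_n: int = 10) -> tuple[int, float]:
    """Mann-Kendall trend test of values against time.

    Returns (S, two-sided p).  S sums the signs of all forward value
    differences after ordering by time.  The p-value uses the exact null
    distribution for tie-free series with n ≤ ``exact_max_n``, otherwise the
    normal approximation with tie-corrected variance and continuity
    correction.
    """
    arr = np.asarray(xs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("xs must be a sequence of (time, value) pairs")
    n = arr.shape[0]
    if n < 3:
        raise ValueError("Mann-Kendall requires at least 3 points")
    t, v = arr[:, 0], arr[:, 1]
    if np.ptp(t) == 0:
        raise ValueError("times must not all be equal")
    order = np.argsort(t, kind="stable")
    v = v[order]
    iu, ju = np.triu_indices(n, k=1)
    s = int(np.sum(np.sign(v[ju] - v[iu])))

    _, tie_counts = np.unique(v, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if not has_ties and n <= exact_max_n:
        return s, _mk_exact_p(s, n)

    var = (n * (n - 1) * (2 * n + 5) - np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5))) / 18.0
    if var <= 0:
        return s, 1.0
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    return s, float(2.0 * stats.norm.sf(abs(z)))


def similarity_slope(xs: Sequence[tuple[float, float]]) -> float:
    """Ordinary least-squares slope of similarity against days, per 100 days."""
    arr = np.asarray(xs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (days, similarity) points")
    t, v = arr[:, 0], arr[:, 1]
    if np.ptp(t) == 0:
        raise ValueError("times must not all be equal")
    slope = stats.linregress(t, v).slope
    return float(slope * 100.0)


def trend_analysis(xs: Sequence[tuple[float, float]]) -> TrendResult:
    """Mann-Kendall test plus OLS slope on a (days, similarity%) series."""
    s, p = mann_kendall(xs)
    return TrendResult(S=s, p_value=p, slope_per_100_days=similarity_slope(xs))


def _check_groups(groups: Sequence[Sequence[float]], min_groups: int = 2) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < min_groups:
        raise ValueError(f"need at least {min_groups} groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("every group must be non-empty")
    return gs


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H (chi-square distributed), df, p."""
    gs = _check_groups(groups)
    if np.ptp(np.concatenate(gs)) == 0:
        # all pooled values identical: no rank variation, H = 0 by convention
        return 0.0, len(gs) - 1, 1.0
    h, p = stats.kruskal(*gs)
    return float(h), len(gs) - 1, float(p)


def scheffe_posthoc(groups: Sequence[Sequence[float]], on_ranks: bool = True) -> dict[tuple[int, int], float]:
    """Scheffé simultaneous pairwise comparisons.

    By default values are rank-transformed first so the procedure is
    coherent with the Kruskal-Wallis omnibus; ``on_ranks=False`` applies the
    classical ANOVA-residual variant to the raw values.  Returns a p-value
    per group pair (i, j), i < j.
    """
    gs = _check_groups(groups, min_groups=3)
    sizes = np.array([g.size for g in gs])
    pooled = np.concatenate(gs)
    if on_ranks:
        pooled = stats.rankdata(pooled)
    split = np.split(pooled, np.cumsum(sizes)[:-1])
    n_total, g = pooled.size, len(gs)
    means = np.array([s.mean() for s in split])
    sse = sum(float(np.sum((s - m) ** 2)) for s, m in zip(split, means))
    df_err = n_total - g
    if df_err <= 0:
        raise ValueError("not enough observations for the error term")
    mse = sse / df_err
    out: dict[tuple[int, int], float] = {}
    for i in range(g):
        for j in range(i + 1, g):
            if mse == 0:
                out[(i, j)] = 1.0 if means[i] == means[j] else 0.0
                continue
            f = (means[i] - means[j]) ** 2 / ((g - 1) * mse * (1.0 / sizes[i] + 1.0 / sizes[j]))
            out[(i, j)] = float(stats.f.sf(f, g - 1, df_err))
    return out


def _pairwise_mean_diff_perm(a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    """One-sided permutation p for mean(a) − mean(b) (add-one estimator)."""
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    total = pooled.sum()
    count = 0
    block = max(1, int(2e7) // n)  # bound scratch memory for very large groups
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, na - 1, axis=1)[:, :na]
        sum_a = pooled[idx].sum(axis=1)
        stat = sum_a / na - (total - sum_a) / (n - na)
        count += int(np.sum(stat >= obs))
        done += m
    return float((1 + count) / (1 + n_perm))


def permutation_test(
    groups: Sequence[Sequence[float]],
    statistic: str = "kruskal_wallis_chi2",
    n_perm: int = 10000,
    seed: int = 0,
) -> dict:
    """Label-permutation tests across groups.

    ``statistic="kruskal_wallis_chi2"`` permutes labels over the pooled
    values and reports the omnibus p = (1 + #{H* ≥ H_obs}) / (1 + n_perm).
    ``statistic="pairwise_mean_diff"`` runs a one-sided permutation test of
    mean(group_i) − mean(group_j) for every pair (ordered so the test asks
    whether the earlier-listed group has larger mean).  All draws are seeded
    and reproducible.
    """
    gs = _check_groups(groups)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if statistic == "kruskal_wallis_chi2":
        obs, _, _ = kruskal_wallis(gs)
        sizes = np.array([g.size for g in gs])
        pooled = np.concatenate(gs)
        ranks = stats.rankdata(pooled)
        n = pooled.size
        # tie correction depends only on the pooled multiset -> permutation-invariant
        _, tc = np.unique(pooled, return_counts=True)
        tie = 1.0 - np.sum(tc**3 - tc) / (n**3 - n)
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(ranks)
            sums = np.add.reduceat(perm, bounds[:-1])
            h = (12.0 / (n * (n + 1))) * np.sum(sums**2 / sizes) - 3.0 * (n + 1)
            count += (h / tie) >= obs - 1e-12
        return {"omnibus": float((1 + count) / (1 + n_perm))}
    if statistic == "pairwise_mean_diff":
        out: dict[tuple[int, int], float] = {}
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                out[(i, j)] = _pairwise_mean_diff_perm(gs[i], gs[j], n_perm, rng)
        return out
    raise ValueError(f"unknown statistic: {statistic!r}")


def similarity_records(
    dm: DistanceMatrix,
    kinship: Optional[pd.DataFrame] = None,
) -> list[SimilarityRecord]:
    """Similarity of every within-subject pair relative to the d0 baseline."""
    d0 = expected_unrelated_distance(dm, kinship)
    diffs = partition_differences(dm)
    names = [f"{s}_{t}" for s, t in zip(dm.labels.subject_id, dm.labels.session_id)]
    return [
        SimilarityRecord(pair=(names[i], names[j]), d1=float(dm.values[i, j]), d0=d0)
        for i, j in diffs.within_pairs
    ]
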