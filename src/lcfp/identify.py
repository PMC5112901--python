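"""Subject-identification statistics for fingerprint collections.

Given one fingerprint per scan, this module computes the pairwise
root-mean-squared-error (RMSE) distance matrix, partitions the pairs into
within-subject and between-subject differences, and quantifies identifiability
by d-prime, leave-one-out cross-validated linear discriminant classification,
and a generalized-extreme-value (GEV) model of the overlap between the two
difference distributions.

The distance layer is deliberately modality-agnostic: every operation accepts
plain equal-length feature vectors (e.g. FA maps or flattened connectivity
matrices) in place of fingerprints, so alternative modalities can be run
through the identical analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy import stats

from .fingerprint import Fingerprint

__all__ = [
    "DistanceMatrix",
    "PairDifferenceSet",
    "GevParams",
    "IdentificationReport",
    "rmse_distance",
    "distance_matrix",
    "partition_differences",
    "dprime",
    "lda_loocv",
    "fit_gev",
    "gev_classification_error",
    "identification_report",
]

logger = logging.getLogger(__name__)

Vector = Union[Fingerprint, np.ndarray, Sequence[float]]


def _as_values(v: Vector) -> np.ndarray:
    if isinstance(v, Fingerprint):
        return v.values
    return np.asarray(v, dtype=float).ravel()


def rmse_distance(a: Vector, b: Vector) -> float:
    """Root-mean-squared error between two feature vectors.

    For fingerprints the atlas hash and normalization state must match; any
    other equal-length vectors are accepted as-is.
    """
    if isinstance(a, Fingerprint) and isinstance(b, Fingerprint):
        if a.atlas_hash != b.atlas_hash:
            raise ValueError("fingerprints sampled on different atlases")
        if a.normalized != b.normalized:
            raise ValueError("fingerprints in different normalization states")
    va, vb = _as_values(a), _as_values(b)
    if va.size != vb.size:
        raise ValueError(f"length mismatch: {va.size} vs {vb.size}")
    return float(np.sqrt(np.mean((va - vb) ** 2)))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise RMSE distances with per-scan labels."""

    values: np.ndarray
    labels: pd.DataFrame  # columns: subject_id, session_id, days

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = v.shape[0]
        if v.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12) or np.any(np.abs(np.diag(v)) > 1e-12) or np.any(v < 0):
            raise ValueError("distance matrix must be symmetric, non-negative, zero-diagonal")
        if len(self.labels) != n:
            raise ValueError("one label row per scan required")
        if not {"subject_id", "session_id"}.issubset(self.labels.columns):
            raise ValueError("labels need subject_id and session_id columns")
        self.values = v

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        names = [f"{s}_{t}" for s, t in zip(self.labels.subject_id, self.labels.session_id)]
        pd.DataFrame(self.values, index=names, columns=names).to_csv(path)


def distance_matrix(fps: Sequence[Vector], labels: Optional[pd.DataFrame] = None) -> DistanceMatrix:
    """All pairwise RMSE distances between scans.

    When ``labels`` is omitted the fingerprints' own metadata is used.
    """
    n = len(fps)
    if labels is None:
        if not all(isinstance(f, Fingerprint) for f in fps):
            raise ValueError("labels required for plain feature vectors")
        labels = pd.DataFrame(
            {
                "subject_id": [f.subject_id for f in fps],
                "session_id": [f.session_id for f in fps],
                "days": [f.days for f in fps],
            }
        )
    vals = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = rmse_distance(fps[i], fps[j])
    return DistanceMatrix(values=vals, labels=labels.reset_index(drop=True))


@dataclass
class PairDifferenceSet:
    """Off-diagonal distances split into within- and between-subject pairs."""

    within: np.ndarray
    between: np.ndarray
    within_pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    between_pairs: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))

    @property
    def n_within(self) -> int:
        return int(np.size(self.within))

    @property
    def n_between(self) -> int:
        return int(np.size(self.between))


def partition_differences(dm: DistanceMatrix) -> PairDifferenceSet:
    """Classify every unordered scan pair as within- or between-subject.

    The two sets cover all C(n, 2) off-diagonal pairs exactly once.
    """
    labels = dm.labels
    if len(dm) < 2:
        raise ValueError("at least two sessions required")
    key = list(zip(labels.subject_id, labels.session_id))
    if len(set(key)) != len(key):
        raise ValueError("duplicate (subject, session) labels")
    subj = labels.subject_id.to_numpy()
    iu, ju = np.triu_indices(len(dm), k=1)
    same = subj[iu] == subj[ju]
    return PairDifferenceSet(
        within=dm.values[iu[same], ju[same]],
        between=dm.values[iu[~same], ju[~same]],
        within_pairs=np.column_stack([iu[same], ju[same]]),
        between_pairs=np.column_stack([iu[~same], ju[~same]]),
    )


def dprime(within: Sequence[float], between: Sequence[float]) -> float:
    """Standardized separation (μ_b − μ_w) / √((σ_b² + σ_w²)/2).

    Sample (n−1) variances are used.
    """
    w = np.asarray(within, dtype=float)
    b = np.asarray(between, dtype=float)
    if w.size < 2 or b.size < 2:
        raise ValueError("both groups need at least two values")
    return float((b.mean() - w.mean()) / np.sqrt((b.var(ddof=1) + w.var(ddof=1)) / 2.0))


def _lda_predict(x: float, n_w: int, s_w: float, ss_w: float, n_b: int, s_b: float, ss_b: float,
                 equal_priors: bool) -> int:
    """1-D LDA decision from sufficient statistics; returns 1 for 'between'.

    Pooled within-class variance, Gaussian classes, empirical priors by
    default (the named default of common LDA implementations).
    """
    mu_w, mu_b = s_w / n_w, s_b / n_b
    ss = (ss_w - n_w * mu_w**2) + (ss_b - n_b * mu_b**2)
    var = ss / (n_w + n_b - 2)
    if var <= 0:
        # degenerate fold: both classes constant; decide by nearest mean
        return int(abs(x - mu_b) < abs(x - mu_w))
    if equal_priors:
        lp_w = lp_b = 0.0
    else:
        lp_w = np.log(n_w / (n_w + n_b))
        lp_b = np.log(n_b / (n_w + n_b))
    score_w = x * mu_w / var - mu_w**2 / (2 * var) + lp_w
    score_b = x * mu_b / var - mu_b**2 / (2 * var) + lp_b
    return int(score_b > score_w)


def lda_loocv(diffs: PairDifferenceSet, equal_priors: bool = False) -> tuple[int, float]:
    """Leave-one-out classification of pair distances as within/between.

    Each held-out distance is classified by a one-dimensional linear
    discriminant (shared pooled variance; class-frequency priors unless
    ``equal_priors``) trained on all remaining distances.  Returns the
    misclassification count and rate.
    """
    w = np.asarray(diffs.within, dtype=float)
    b = np.asarray(diffs.between, dtype=float)
    if w.size == 0 or b.size == 0:
        raise ValueError("both classes must be non-empty")
    if w.size < 2 or b.size < 2:
        raise ValueError("leave-one-out needs at least two values per class")
    n_w, n_b = w.size, b.size
    s_w, s_b = w.sum(), b.sum()
    ss_w, ss_b = np.sum(w**2), np.sum(b**2)
    errors = 0
    for x in w:
        pred = _lda_predict(x, n_w - 1, s_w - x, ss_w - x**2, n_b, s_b, ss_b, equal_priors)
        errors += pred == 1
    for x in b:
        pred = _lda_predict(x, n_w, s_w, ss_w, n_b - 1, s_b - x, ss_b - x**2, equal_priors)
        errors += pred == 0
    total = n_w + n_b
    return int(errors), errors / total


@dataclass(frozen=True)
class GevParams:
    """Generalized extreme value parameters: shape k (>0), scale, location.

    Sign convention follows the common k-parameterization in which k > 0
    gives a heavy right tail with support x > mu - sigma/k (the constraint
    used here to respect the non-negativity of distance distributions).
    """

    k: float
    sigma: float
    mu: float

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.sigma > 0):
            raise ValueError("require k > 0 and sigma > 0")

    @property
    def scipy_c(self) -> float:
        """scipy.stats.genextreme shape (c = −k)."""
        return -self.k

    def frozen(self):
        return stats.genextreme(self.scipy_c, loc=self.mu, scale=self.sigma)


def fit_gev(samples: Sequence[float], k_min: float = 1e-6) -> GevParams:
    """Maximum-likelihood GEV fit with the shape constrained to k > 0.

    Uses the unconstrained MLE as the initializer and a box-bounded
    quasi-Newton refinement (k ≥ ``k_min``) of the negative log-likelihood.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2 or np.ptp(x) <= 0:
        raise ValueError("degenerate sample: need at least two distinct values")
    if x.size < 10:
        warnings.warn("fewer than 10 samples: GEV fit will be unstable", stacklevel=2)

    # initializer: unconstrained scipy MLE, fall back to moment-style guess
    try:
        c0, mu0, sig0 = stats.genextreme.fit(x)
        k0 = -c0
    except Exception:  # pragma: no cover - scipy fit rarely raises
        k0, sig0, mu0 = 0.1, x.std(ddof=1), x.mean()
    if not np.isfinite([k0, sig0, mu0]).all() or k0 <= k_min:
        k0 = max(0.1, k_min * 10)
        sig0 = x.std(ddof=1) * np.sqrt(6) / np.pi
        mu0 = x.mean() - 0.5772 * sig0
    # ensure the starting point has all samples inside the support x > mu - sigma/k
    lo = x.min()
    if mu0 - sig0 / k0 >= lo:
        mu0 = lo + sig0 / k0 - 1e-6 * sig0

    def nll(theta: np.ndarray) -> float:
        k, log_sig, mu = theta
        logpdf = stats.genextreme.logpdf(x, -k, loc=mu, scale=np.exp(log_sig))
        if not np.all(np.isfinite(logpdf)):
            return 1e10
        return -float(np.sum(logpdf))

    res = optimize.minimize(
        nll,
        x0=np.array([k0, np.log(sig0), mu0]),
        method="L-BFGS-B",
        bounds=[(k_min, 20.0), (None, None), (None, None)],
    )
    if not np.isfinite(res.fun) or res.fun >= 1e10:
        raise RuntimeError(f"GEV fit failed to converge: {res.message}")
    k, log_sig, mu = res.x
    return GevParams(k=float(k), sigma=float(np.exp(log_sig)), mu=float(mu))


def gev_classification_error(
    gw: GevParams, gb: GevParams, rng: Optional[np.random.Generator] = None
) -> float:
    """P(X_w > X_b) for independent GEV-distributed difference variables.

    Computed as ∫₀¹ F_b(Q_w(u)) du (the expectation of the between-subject
    CDF at a within-subject draw) by adaptive quadrature to 1e-10 absolute
    tolerance; falls back to seeded Monte-Carlo if the quadrature fails.
    """
    fw, fb = gw.frozen(), gb.frozen()

    def integrand(u: float) -> float:
        return float(fb.cdf(fw.ppf(u)))

    try:
        val, err = integrate.quad(integrand, 0.0, 1.0, epsabs=1e-10, epsrel=1e-10, limit=500)
        if err > 1e-6:
            raise RuntimeError(f"quadrature error estimate too large: {err}")
        return float(np.clip(val, 0.0, 1.0))
    except Exception as exc:  # pragma: no cover - quadrature on this integrand is robust
        logger.warning("quadrature failed (%s); using Monte-Carlo fallback", exc)
        rng = rng or np.random.default_rng(0)
        n = 10**6
        xw = fw.ppf(rng.random(n))
        xb = fb.ppf(rng.random(n))
        return float(np.mean(xw > xb))


@dataclass
class IdentificationReport:
    """The full identification analysis for one scan collection."""

    dprime: float
    loocv_errors: int
    loocv_rate: float
    gev_within: GevParams
    gev_between: GevParams
    modeled_error: float
    n_within: int
    n_between: int

    def to_dict(self) -> dict:
        return {
            "dprime": self.dprime,
            "loocv_errors": self.loocv_errors,
            "loocv_rate": self.loocv_rate,
            "gev_within": {"k": self.gev_within.k, "sigma": self.gev_within.sigma, "mu": self.gev_within.mu},
            "gev_between": {"k": self.gev_between.k, "sigma": self.gev_between.sigma, "mu": self.gev_between.mu},
            "modeled_error": self.modeled_error,
            "n_within": self.n_within,
            "n_between": self.n_between,
        }


def identification_report(dm: DistanceMatrix, equal_priors: bool = False) -> IdentificationReport:
    """Run the complete identification analysis on a distance matrix."""
    diffs = partition_differences(dm)
    d = dprime(diffs.within, diffs.between)
    n_err, rate = lda_loocv(diffs, equal_priors=equal_priors)
    gw = fit_gev(diffs.within)
    gb = fit_gev(diffs.between)
    modeled = gev_classification_error(gw, gb)
    return IdentificationReport(
        dprime=d,
        loocv_errors=n_err,
        loocv_rate=rate,
        gev_within=gw,
        gev_between=gb,
        modeled_error=modeled,
        n_within=diffs.n_within,
        n_between=diffs.n_between,
    )
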