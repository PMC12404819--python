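"""Covariance-matrix similarity: common-subspace variance comparison, random
skewers, eigenvector correlations, with REML-MVN resampling and BCa intervals.

The common-subspace (Krzanowski-style) comparison projects two covariance
matrices onto the same orthonormal reference basis — by default the leading
eigenvectors of an independently estimated third matrix — and correlates the
log variances along those axes. Uncertainty is propagated by resampling
matrices from the multivariate-normal sampling distribution of their REML (or
moment) estimates and re-running the comparison on every draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._geometry import nearest_psd, unvech, vech
from .varcomp import CovarianceMatrix, FactorModel

__all__ = [
    "reference_basis",
    "krzanowski_compare",
    "SubspaceComparison",
    "reml_mvn_resample",
    "ResampleResult",
    "bca_interval",
    "vector_correlation",
    "vector_angle",
    "random_skewers",
    "SkewersResult",
    "subspace_comparison_with_ci",
    "eigenvector_correlation_with_ci",
]


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, CovarianceMatrix):
        return m.values
    return np.asarray(m, dtype=float)


# ---------------------------------------------------------------------------
# reference basis and subspace comparison


def reference_basis(m, q: int) -> np.ndarray:
    """First q unit eigenvectors of a covariance matrix, descending eigenvalue.

    Signs follow the largest-magnitude-element-positive convention (ties by
    first index), so the basis does not depend on the sign returned by the
    eigendecomposition. Raises if q exceeds the numerical rank, since
    variances compared along null directions are meaningless — restrict the
    comparison to the dimensions the matrices actually share.
    """
    mat = _as_matrix(m)
    vals, vecs = np.linalg.eigh(0.5 * (mat + mat.T))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    rank = int((vals > 1e-10 * max(vals[0], 1e-300)).sum())
    if q > rank:
        raise ValueError(
            f"q={q} exceeds the numerical rank ({rank}) of the reference matrix; "
            "restrict the comparison to the dimensions shared by all matrices"
        )
    k = vecs[:, :q].copy()
    for j in range(q):
        i = int(np.argmax(np.abs(k[:, j])))
        if k[i, j] < 0:
            k[:, j] = -k[:, j]
    return k


@dataclass
class SubspaceComparison:
    """Log-variances of two matrices along a shared orthonormal basis."""

    reference_vectors: np.ndarray  # p x q
    log_variances_a: np.ndarray
    log_variances_b: np.ndarray
    r: float
    b: float
    q_used: int
    degenerate: bool = False
    ci_r: tuple[float, float] | None = None
    ci_b: tuple[float, float] | None = None
    ci_level: float | None = None

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "b": self.b,
            "q": self.q_used,
            "degenerate": self.degenerate,
            "ci_r": list(self.ci_r) if self.ci_r else None,
            "ci_b": list(self.ci_b) if self.ci_b else None,
            "ci_level": self.ci_level,
            "log_variances_a": self.log_variances_a.tolist(),
            "log_variances_b": self.log_variances_b.tolist(),
        }


def _log_variances(mat: np.ndarray, k: np.ndarray) -> np.ndarray:
    v = np.einsum("pq,pr,rq->q", k, mat, k)
    if (v <= 0).any():
        raise ValueError(
            "non-positive projected variance along a reference axis; "
            "log variance undefined (reduce q or check matrix rank)"
        )
    return np.log(v)


def krzanowski_compare(a, b, k: np.ndarray) -> SubspaceComparison:
    """Correlation and slope of log variances along a shared basis.

    vA = diag(K' A K), vB = diag(K' B K); r is the Pearson correlation of
    log vA with log vB and b the OLS slope of log vB on log vA, i.e. A plays
    the predictor role (for a D-versus-G comparison pass A = D, B = G: the
    slope measures how developmental variance predicts genetic variance).
    Zero variance in either log series is degenerate: r is reported as 0 with
    the ``degenerate`` flag set.
    """
    a_mat, b_mat = _as_matrix(a), _as_matrix(b)
    k = np.asarray(k, dtype=float)
    if not np.allclose(k.T @ k, np.eye(k.shape[1]), atol=1e-8):
        raise ValueError("reference vectors must be orthonormal")
    q = k.shape[1]
    if q < 3:
        warnings.warn("fewer than 3 reference axes: correlation unstable", stacklevel=2)
    log_va = _log_variances(a_mat, k)
    log_vb = _log_variances(b_mat, k)
    var_a = log_va.var()
    var_b = log_vb.var()
    degenerate = var_a == 0 or var_b == 0
    r = 0.0 if degenerate else float(np.corrcoef(log_va, log_vb)[0, 1])
    b_slope = 0.0
    if var_a > 0:
        ca = log_va - log_va.mean()
        b_slope = float((ca * (log_vb - log_vb.mean())).sum() / (ca**2).sum())
    return SubspaceComparison(
        reference_vectors=k,
        log_variances_a=log_va,
        log_variances_b=log_vb,
        r=r,
        b=b_slope,
        q_used=q,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# REML-MVN resampling


@dataclass
class ResampleResult:
    """Matrices drawn from the MVN sampling distribution of an estimate.

    ``draws`` is (n_samples, p, p) in the full shape-variable space; non-PSD
    reconstructions were projected to the nearest PSD matrix (eigenvalue
    clipping at zero) and counted in ``n_clipped``.
    """

    draws: np.ndarray
    n_clipped: int
    seed: int

    @property
    def n_samples(self) -> int:
        return self.draws.shape[0]


def reml_mvn_resample(fit, n_samples: int, seed: int = 0) -> ResampleResult:
    """Draw covariance matrices from the MVN distribution of their estimate.

    Sampling is on the covariance-parameter ('G-') scale: vech of the matrix
    is drawn from a normal centered at the estimate with the fit's sampling
    covariance, then reassembled. Accepts a CovarianceMatrix carrying a
    sampling covariance (moment/Wishart form) or a FactorModel carrying the
    delta-method covariance of its implied matrix. Warns when more than half
    the draws require PSD clipping.
    """
    if isinstance(fit, FactorModel):
        center = fit.implied_reduced(include_specific=True)
        cov = fit.vech_sampling_cov
        basis = fit.basis
    elif isinstance(fit, CovarianceMatrix):
        center = fit.reduced if fit.reduced is not None else fit.values
        cov = fit.sampling_cov
        basis = fit.basis
    else:
        raise TypeError("fit must be a CovarianceMatrix or FactorModel")
    if cov is None:
        raise ValueError("fit carries no sampling covariance; cannot resample")
    pt = center.shape[0]
    mean = vech(center)
    cov = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    root = vecs * np.sqrt(vals)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, len(mean)))
    vech_draws = mean + z @ root.T
    draws = np.empty((n_samples, basis.shape[0], basis.shape[0]))
    n_clipped = 0
    for i in range(n_samples):
        mat = unvech(vech_draws[i], pt)
        mat, clipped = nearest_psd(mat)
        n_clipped += clipped
        draws[i] = basis @ mat @ basis.T
    if n_samples and n_clipped > 0.5 * n_samples:
        warnings.warn(
            f"{n_clipped}/{n_samples} MVN draws required PSD clipping; "
            "normal approximation may be unreliable",
            stacklevel=2,
        )
    return ResampleResult(draws=draws, n_clipped=n_clipped, seed=seed)


# ---------------------------------------------------------------------------
# BCa intervals


def bca_interval(
    statistic_samples: np.ndarray,
    observed: float,
    jackknife_values: np.ndarray | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Bias-corrected and accelerated interval from resampled statistics.

    z0 comes from the fraction of samples below the observed value;
    the acceleration a from the jackknife skewness (a = 0 if no jackknife
    values are supplied). With z0 = a = 0 this reduces to the plain
    percentile interval. Identical samples give the degenerate interval
    (observed, observed).
    """
    samples = np.asarray(statistic_samples, dtype=float)
    samples = samples[np.isfinite(samples)]
    if len(samples) < 100:
        raise ValueError("need at least 100 resampled values for a BCa interval")
    if np.allclose(samples, samples[0]):
        return float(observed), float(observed)
    frac = (samples < observed).mean()
    frac = min(max(frac, 1.0 / (len(samples) + 1)), 1 - 1.0 / (len(samples) + 1))
    z0 = stats.norm.ppf(frac)
    a = 0.0
    if jackknife_values is not None and len(jackknife_values) > 2:
        jk = np.asarray(jackknife_values, dtype=float)
        jk = jk[np.isfinite(jk)]
        d = jk.mean() - jk
        denom = 6.0 * (d**2).sum() ** 1.5
        if denom > 0:
            a = float((d**3).sum() / denom)
    alpha = 1.0 - level
    lo_hi = []
    for q in (alpha / 2, 1 - alpha / 2):
        z = stats.norm.ppf(q)
        adj = z0 + (z0 + z) / (1 - a * (z0 + z))
        lo_hi.append(float(np.quantile(samples, stats.norm.cdf(adj))))
    return lo_hi[0], lo_hi[1]


# ---------------------------------------------------------------------------
# vector correlation and random skewers


def vector_correlation(v1: np.ndarray, v2: np.ndarray) -> float:
    """Absolute cosine similarity |v1 . v2| / (|v1| |v2|), in [0, 1]."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("vector correlation undefined for zero vectors")
    return float(min(abs(v1 @ v2) / (n1 * n2), 1.0))


def vector_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle in degrees corresponding to the absolute cosine similarity."""
    return float(np.degrees(np.arccos(vector_correlation(v1, v2))))


@dataclass
class SkewersResult:
    mean_response_correlation: float
    p_value: float
    n_vectors: int
    seed: int
    method: str
    null: str

    def to_dict(self) -> dict:
        return {
            "mean_response_correlation": self.mean_response_correlation,
            "p_value": self.p_value,
            "n_vectors": self.n_vectors,
            "seed": self.seed,
            "method": self.method,
            "null": self.null,
        }


def _random_unit_vectors(rng, n: int, p: int, method: str) -> np.ndarray:
    if method == "uniform":
        v = rng.uniform(-1.0, 1.0, size=(n, p))
    elif method == "gaussian":
        v = rng.standard_normal((n, p))
    else:
        raise ValueError(f"unknown skewer method {method!r}")
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def random_skewers(
    a,
    b,
    n_vectors: int = 10000,
    seed: int = 0,
    method: str = "uniform",
    null: str = "analytic",
) -> SkewersResult:
    """Average response-vector correlation under random selection gradients.

    Each random unit vector beta yields responses A beta and B beta; their
    absolute cosine similarity is averaged over vectors. The p-value is the
    probability that the absolute cosine of two independent random directions
    in p dimensions exceeds the observed mean (cos^2 ~ Beta(1/2, (p-1)/2));
    ``null='montecarlo'`` replaces the analytic tail with simulated pairs.
    """
    a_mat, b_mat = _as_matrix(a), _as_matrix(b)
    if a_mat.shape != b_mat.shape:
        raise ValueError("matrices must have the same dimension")
    p = a_mat.shape[0]
    rng = np.random.default_rng(seed)
    betas = _random_unit_vectors(rng, n_vectors, p, method)
    ra = betas @ a_mat
    rb = betas @ b_mat
    num = np.abs(np.einsum("ij,ij->i", ra, rb))
    den = np.linalg.norm(ra, axis=1) * np.linalg.norm(rb, axis=1)
    good = den > 0
    corr = np.ones(n_vectors)
    corr[good] = np.clip(num[good] / den[good], 0.0, 1.0)
    mean_corr = float(corr.mean())
    if null == "analytic":
        p_value = float(stats.beta.sf(mean_corr**2, 0.5, (p - 1) / 2.0))
    elif null == "montecarlo":
        u = _random_unit_vectors(rng, n_vectors, p, method)
        v = _random_unit_vectors(rng, n_vectors, p, method)
        null_corr = np.abs(np.einsum("ij,ij->i", u, v))
        p_value = float((1 + (null_corr >= mean_corr).sum()) / (1 + n_vectors))
    else:
        raise ValueError(f"unknown null {null!r}")
    p_value = max(p_value, np.finfo(float).tiny)
    return SkewersResult(
        mean_response_correlation=mean_corr,
        p_value=p_value,
        n_vectors=n_vectors,
        seed=seed,
        method=method,
        null=null,
    )


# ---------------------------------------------------------------------------
# resampling-based confidence intervals for the headline comparisons


def subspace_comparison_with_ci(
    d: CovarianceMatrix,
    g: CovarianceMatrix,
    p_ref: CovarianceMatrix,
    q: int = 6,
    n_samples: int = 10000,
    seed: int = 0,
    level: float = 0.95,
    jackknife_r: np.ndarray | None = None,
    jackknife_b: np.ndarray | None = None,
    draws: dict[str, np.ndarray] | None = None,
) -> SubspaceComparison:
    """Common-subspace comparison of D and G along P's leading eigenvectors,
    with BCa confidence intervals from REML-MVN resampling.

    The reference basis is re-derived from the resampled P on every draw.
    ``draws`` may supply pre-computed joint draws of the three matrices
    (dict with keys 'D', 'G', 'P' of (n, p, p) arrays, e.g. from
    ``varcomp.resample_dgp``); joint draws preserve the strong sampling
    correlation between the P and G estimates, which per-matrix independent
    resampling misses. Without ``draws`` the three matrices are resampled
    independently from their own sampling covariances.
    """
    k = reference_basis(p_ref, q)
    observed = krzanowski_compare(d, g, k)
    if draws is not None:
        d_draws, g_draws, p_draws = draws["D"], draws["G"], draws["P"]
        n_samples = d_draws.shape[0]
    else:
        d_draws = reml_mvn_resample(d, n_samples, seed=seed).draws
        g_draws = reml_mvn_resample(g, n_samples, seed=seed + 1).draws
        p_draws = reml_mvn_resample(p_ref, n_samples, seed=seed + 2).draws
    r_draws = np.full(n_samples, np.nan)
    b_draws = np.full(n_samples, np.nan)
    for i in range(n_samples):
        try:
            k_i = reference_basis(p_draws[i], q)
            cmp_i = krzanowski_compare(d_draws[i], g_draws[i], k_i)
        except ValueError:
            continue
        if not cmp_i.degenerate:
            r_draws[i] = cmp_i.r
            b_draws[i] = cmp_i.b
    observed.ci_r = bca_interval(r_draws, observed.r, jackknife_r, level)
    observed.ci_b = bca_interval(b_draws, observed.b, jackknife_b, level)
    observed.ci_level = level
    return observed


def eigenvector_correlation_with_ci(
    d: CovarianceMatrix,
    g: CovarianceMatrix,
    n_samples: int = 10000,
    seed: int = 0,
    level: float = 0.95,
    jackknife_values: np.ndarray | None = None,
) -> dict:
    """Vector correlation between dmax and gmax with a resampling CI.

    The leading eigenvector of each resampled matrix is extracted per draw;
    the correlation's BCa interval and the corresponding angle interval are
    reported (angle bounds are the transforms of the correlation bounds).
    """
    observed = vector_correlation(d.leading_eigenvector, g.leading_eigenvector)
    rs_d = reml_mvn_resample(d, n_samples, seed=seed)
    rs_g = reml_mvn_resample(g, n_samples, seed=seed + 1)
    draws = np.empty(n_samples)
    for i in range(n_samples):
        vd = np.linalg.eigh(rs_d.draws[i])[1][:, -1]
        vg = np.linalg.eigh(rs_g.draws[i])[1][:, -1]
        draws[i] = vector_correlation(vd, vg)
    ci = bca_interval(draws, observed, jackknife_values, level)
    angle = float(np.degrees(np.arccos(min(observed, 1.0))))
    return {
        "r": observed,
        "angle_deg": angle,
        "ci_r": ci,
        "ci_angle_deg": (
            float(np.degrees(np.arccos(min(ci[1], 1.0)))),
            float(np.degrees(np.arccos(min(max(ci[0], -1.0), 1.0)))),
        ),
        "n_samples": n_samples,
        "seed": seed,
        "level": level,
    }
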