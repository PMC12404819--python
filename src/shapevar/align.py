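"""Alignment of shape-change vectors with covariance structure.

Latitudinal and thermal shape-change vectors are estimated by multivariate
least squares on aggregated Procrustes shapes; their alignment with a
covariance matrix M is measured by the e_beta statistic

    e_beta = beta' M beta / |beta|^2,   M scaled to unit trace,

the fraction of the (trace-normalized) variance in M captured by the
direction beta: it is bounded by the extreme eigenvalues of the scaled
matrix and attains the leading eigenvalue when beta is the leading
eigenvector. Significance comes from resampling nulls: by default the
elements of beta are permuted (preserving its norm and marginal
distribution while destroying the landmark structure); isotropic random
directions are available as an alternative null. Angles between vectors are
tested the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .procrustes import AlignedDataset
from .compare import vector_correlation
from .varcomp import CovarianceMatrix

__all__ = [
    "ShapeChangeVector",
    "AlignmentResult",
    "fit_shape_regression",
    "e_beta",
    "e_beta_test",
    "angle_test",
]


@dataclass
class ShapeChangeVector:
    """Multivariate regression coefficient vector for one covariate."""

    beta: np.ndarray  # p-vector, Procrustes units per covariate unit
    covariate: str  # 'latitude' | 'temperature' | 'custom'
    model_terms: list[str] = field(default_factory=list)
    n_units: int = 0

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.beta))

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate,
            "norm": self.norm,
            "model_terms": self.model_terms,
            "n_units": self.n_units,
            "beta": self.beta.tolist(),
        }


@dataclass
class AlignmentResult:
    statistic_name: str  # 'e_beta' | 'angle'
    observed: float
    null_samples: np.ndarray
    p_value: float
    reference: str  # 'D' | 'G' | 'dmax' | 'gmax' | 'custom'
    n_resamples: int
    seed: int
    null_scheme: str = "permute"

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "p_value": self.p_value,
            "reference": self.reference,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "null_scheme": self.null_scheme,
            "null_mean": float(np.mean(self.null_samples)),
            "null_sd": float(np.std(self.null_samples, ddof=1)),
        }


def _dummies(values: pd.Series) -> np.ndarray:
    levels = pd.unique(values.dropna())
    if len(levels) < 2:
        return np.empty((len(values), 0))
    return np.column_stack([(values == lev).to_numpy(float) for lev in levels[1:]])


def fit_shape_regression(
    aligned: AlignedDataset,
    design,
    covariate: str = "latitude",
    aggregation: str | None = None,
) -> ShapeChangeVector:
    """Shape-change vector for a covariate by multivariate least squares.

    covariate='latitude' aggregates to family mean shapes (across
    temperatures) and regresses on latitude with log centroid size partialled
    out; covariate='temperature' aggregates to individual mean shapes and
    fits a two-level temperature contrast (low -> high) with log centroid
    size and population partialled out. Raises if the focal covariate does
    not vary (collinear design).
    """
    if aggregation is None:
        aggregation = "by_family" if covariate == "latitude" else "by_individual"
    keys = aligned.keys.copy()
    keys["_row"] = np.arange(len(keys))
    keys["_logcs"] = np.log(aligned.centroid_sizes)
    merged = keys.merge(design.table, on="specimen_id", how="left")
    y = aligned.shape_coords

    if aggregation == "by_family":
        if "family_id" not in merged.columns:
            raise ValueError("design table lacks family_id for family aggregation")
        merged = merged.dropna(subset=["family_id"])
        groups = merged.groupby("family_id")
        unit_col = "family_id"
    elif aggregation == "by_individual":
        groups = merged.groupby("specimen_id")
        unit_col = "specimen_id"
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")

    rows = []
    shapes = []
    for unit, sub in groups:
        shapes.append(y[sub["_row"].to_numpy()].mean(axis=0))
        rows.append(
            {
                "unit": unit,
                "logcs": sub["_logcs"].mean(),
                "latitude": sub["latitude"].mean() if "latitude" in sub else np.nan,
                "temperature": sub["temperature"].mean() if "temperature" in sub else np.nan,
                "population_id": sub["population_id"].iloc[0]
                if "population_id" in sub
                else None,
            }
        )
    units = pd.DataFrame(rows)
    shapes = np.asarray(shapes)

    x_cols = [np.ones(len(units)), units["logcs"].to_numpy() - units["logcs"].mean()]
    terms = ["intercept", "log centroid size"]
    if covariate == "latitude":
        focal = units["latitude"].to_numpy(dtype=float)
        keep = ~np.isnan(focal)
        units, shapes, focal = units[keep], shapes[keep], focal[keep]
        x_cols = [c[keep] for c in x_cols]
        x_cols.append(focal - focal.mean())
        terms.append("latitude")
    elif covariate == "temperature":
        temps = np.sort(units["temperature"].dropna().unique())
        if len(temps) < 2:
            raise ValueError("temperature does not vary; shape vector inestimable")
        contrast = (units["temperature"].to_numpy(dtype=float) == temps[-1]).astype(float)
        x_cols.append(contrast)
        terms.append("temperature")
        if units["population_id"].nunique() > 1:
            x_cols.append(_dummies(units["population_id"]))
            terms.append("population")
    else:
        raise ValueError(f"unknown covariate {covariate!r}")

    x = np.column_stack([np.atleast_2d(c).T if np.ndim(c) == 1 else c for c in x_cols])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"collinear design for covariate {covariate!r} (rank {rank} < {x.shape[1]})"
        )
    coef, _, _, _ = np.linalg.lstsq(x, shapes, rcond=None)
    focal_idx = 2  # intercept, size, then the focal covariate column
    beta = coef[focal_idx]
    if float(np.linalg.norm(beta)) == 0.0:
        raise ValueError("estimated shape-change vector is exactly zero")
    return ShapeChangeVector(
        beta=beta, covariate=covariate, model_terms=terms, n_units=len(units)
    )


def _beta_array(beta) -> np.ndarray:
    if isinstance(beta, ShapeChangeVector):
        return beta.beta
    return np.asarray(beta, dtype=float)


def _scaled_matrix(m) -> np.ndarray:
    mat = m.values if isinstance(m, CovarianceMatrix) else np.asarray(m, dtype=float)
    tr = np.trace(mat)
    if tr <= 0:
        raise ValueError("matrix has non-positive trace")
    return mat / tr


def e_beta(beta, m) -> float:
    """Fraction of (trace-scaled) variance in M along the direction beta.

    Scale-invariant in beta; equals 1/p for an isotropic matrix and the
    leading eigenvalue of the trace-scaled matrix when beta is its leading
    eigenvector (Rayleigh quotient).
    """
    b = _beta_array(beta)
    norm2 = float(b @ b)
    if norm2 == 0:
        raise ValueError("e_beta undefined for a zero vector")
    mat = _scaled_matrix(m)
    return float(b @ mat @ b / norm2)


def _null_vectors(
    rng: np.random.Generator, b: np.ndarray, n: int, scheme: str
) -> np.ndarray:
    if scheme == "permute":
        return rng.permuted(np.tile(b, (n, 1)), axis=1)
    if scheme == "isotropic":
        v = rng.standard_normal((n, len(b)))
        return v / np.linalg.norm(v, axis=1, keepdims=True)
    raise ValueError(f"unknown null scheme {scheme!r}")


def e_beta_test(
    beta,
    m,
    n_resamples: int = 10000,
    seed: int = 0,
    null: str = "permute",
    reference: str = "D",
) -> AlignmentResult:
    """One-sided resampling test of whether e_beta exceeds chance alignment.

    Null vectors are element permutations of beta (default) or isotropic
    random directions; p = (1 + #{null >= observed}) / (1 + n_resamples).
    """
    b = _beta_array(beta)
    mat = _scaled_matrix(m)
    observed = e_beta(b, mat)
    rng = np.random.default_rng(seed)
    nulls = _null_vectors(rng, b, n_resamples, null)
    quad = np.einsum("ij,jk,ik->i", nulls, mat, nulls)
    norm2 = np.einsum("ij,ij->i", nulls, nulls)
    null_vals = quad / norm2
    p = float((1 + (null_vals >= observed).sum()) / (1 + n_resamples))
    return AlignmentResult(
        statistic_name="e_beta",
        observed=observed,
        null_samples=null_vals,
        p_value=p,
        reference=reference,
        n_resamples=n_resamples,
        seed=seed,
        null_scheme=null,
    )


def angle_test(
    beta,
    v: np.ndarray,
    n_resamples: int = 10000,
    seed: int = 0,
    null: str = "permute",
    reference: str = "dmax",
) -> AlignmentResult:
    """One-sided test of the angle between a shape vector and a direction.

    Small angles indicate alignment; the null randomizes both vectors
    (element permutation by default, isotropic directions optionally) and
    p = (1 + #{null angle <= observed}) / (1 + n_resamples).
    """
    b = _beta_array(beta)
    v = np.asarray(v, dtype=float)
    observed = float(np.degrees(np.arccos(vector_correlation(b, v))))
    rng = np.random.default_rng(seed)
    nb = _null_vectors(rng, b, n_resamples, null)
    nv = _null_vectors(rng, v, n_resamples, null)
    cosines = np.abs(np.einsum("ij,ij->i", nb, nv)) / (
        np.linalg.norm(nb, axis=1) * np.linalg.norm(nv, axis=1)
    )
    null_angles = np.degrees(np.arccos(np.clip(cosines, 0.0, 1.0)))
    p = float((1 + (null_angles <= observed).sum()) / (1 + n_resamples))
    return AlignmentResult(
        statistic_name="angle",
        observed=observed,
        null_samples=null_angles,
        p_value=p,
        reference=reference,
        n_resamples=n_resamples,
        seed=seed,
        null_scheme=null,
    )
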