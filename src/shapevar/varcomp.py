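"""Developmental (D), genetic (G) and phenotypic (P) covariance matrices.

Estimation model
----------------
After simultaneous GPA the records are projected onto the orthonormal tangent
basis of the consensus shape (dimension p_t = 2k - 4), where the covariance
structure is full-dimensional; estimates are embedded back into the p = 2k
shape-variable space for reporting. For individual i, side s, replicate r,

    z_{i,s,r} = fixed effects + d_{i,s} + eps_{i,s,r}

with developmental deviations d ~ N(0, D) and heteroscedastic measurement
error eps ~ N(0, diag(sigma^2)) (one error variance per tangent coordinate).
D is identified from the individual x side interaction via signed left/right
contrasts; the among-individual matrix P and the between-family (broad-sense)
matrix G come from the corresponding levels of the replicate/side/family
hierarchy with fixed effects (log centroid size, temperature, population,
cohort where present) removed by least squares.

Two estimation paths are provided for each matrix: closed-form moment
(ANOVA-type) estimators, and restricted maximum likelihood by quasi-Newton
optimization of the Wishart form of the residual likelihood; on balanced
designs the two coincide. Reduced-rank (factor-analytic) covariance models
C = Lambda Lambda' + diag(psi) support AIC-based rank selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from ._geometry import (
    effective_rank,
    nearest_psd,
    normalize,
    tangent_basis,
    unvech,
    vech,
    vech_indices,
    wishart_vech_cov,
)
from .procrustes import AlignedDataset

__all__ = [
    "CovarianceMatrix",
    "FactorModel",
    "estimate_D",
    "estimate_P",
    "estimate_G",
    "estimate_dgp",
    "jackknife_dgp",
    "fit_factor_model",
    "select_rank",
    "reconstruct_cov",
]


class EstimationError(ValueError):
    """Inestimable component or non-convergence."""


# ---------------------------------------------------------------------------
# result containers


@dataclass
class CovarianceMatrix:
    """A labeled symmetric PSD covariance matrix of shape variables.

    ``values`` is p x p in the full shape-variable space; ``reduced`` holds the
    same matrix in the tangent-basis coordinates (``basis`` maps between them,
    values = basis @ reduced @ basis.T). ``sampling_cov`` (when available) is
    the sampling covariance of vech(reduced), used for REML-MVN resampling.
    """

    label: str  # 'D' | 'G' | 'P' | 'other'
    values: np.ndarray
    selected_rank: int
    fixed_effects_adjusted_for: list[str]
    n_units: int
    basis: np.ndarray | None = None
    reduced: np.ndarray | None = None
    sampling_cov: np.ndarray | None = None
    meas_variances: np.ndarray | None = None
    method: str = ""

    def __post_init__(self) -> None:
        self.values = 0.5 * (self.values + self.values.T)
        tr = np.trace(self.values)
        vals = np.linalg.eigvalsh(self.values)
        if tr > 0 and vals.min() < -1e-8 * tr:
            warnings.warn(
                f"{self.label} matrix has negative eigenvalue {vals.min():.3e} "
                f"(trace {tr:.3e})",
                stacklevel=2,
            )

    @property
    def trace(self) -> float:
        return float(np.trace(self.values))

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues/vectors in descending order, sign convention applied."""
        vals, vecs = np.linalg.eigh(self.values)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        for j in range(vecs.shape[1]):
            i = np.argmax(np.abs(vecs[:, j]))
            if vecs[i, j] < 0:
                vecs[:, j] = -vecs[:, j]
        return vals, vecs

    @property
    def leading_eigenvector(self) -> np.ndarray:
        return self.eigen()[1][:, 0]

    def to_dict(self) -> dict:
        vals, _ = self.eigen()
        return {
            "label": self.label,
            "trace": self.trace,
            "selected_rank": self.selected_rank,
            "effective_rank": effective_rank(self.values),
            "n_units": self.n_units,
            "method": self.method,
            "fixed_effects_adjusted_for": self.fixed_effects_adjusted_for,
            "eigenvalues": vals.tolist(),
            "values": self.values.tolist(),
        }


@dataclass
class FactorModel:
    """Reduced-rank covariance fit C = Lambda Lambda' + diag(psi).

    Loadings and variances are expressed in the tangent-basis coordinates;
    ``basis`` embeds them back into shape-variable space.
    """

    loadings: np.ndarray  # p_t x m
    specific_variances: np.ndarray  # p_t
    residual_variances: np.ndarray | None  # p_t measurement-level, if modeled
    loglik: float
    n_params: int
    converged: bool
    basis: np.ndarray
    structure: str
    label: str
    n_units: int
    param_sampling_cov: np.ndarray | None = None
    vech_sampling_cov: np.ndarray | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def m(self) -> int:
        return self.loadings.shape[1]

    def implied_reduced(self, include_specific: bool = True) -> np.ndarray:
        c = self.loadings @ self.loadings.T
        if include_specific:
            c = c + np.diag(self.specific_variances)
        return c


# ---------------------------------------------------------------------------
# data preparation


def _tangent(aligned: AlignedDataset) -> tuple[np.ndarray, np.ndarray]:
    mean = normalize(aligned.consensus)
    basis = tangent_basis(mean)
    z = (aligned.shape_coords - aligned.consensus.reshape(-1)) @ basis
    return basis, z


def _merge_design(keys: pd.DataFrame, design) -> pd.DataFrame:
    df = keys.copy()
    if design is not None:
        df = df.merge(design.table, on="specimen_id", how="left")
    return df


def _residualize(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, int]:
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta, int(rank)


def _dummies(values: pd.Series) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    levels = pd.unique(values.dropna())
    if len(levels) < 2:
        return np.empty((len(values), 0))
    cols = [(values == lev).to_numpy(float) for lev in levels[1:]]
    return np.column_stack(cols)


@dataclass
class _AsymmetryStats:
    basis: np.ndarray
    contrasts_resid: np.ndarray  # n_ind x p_t, (right - left) cell-mean contrasts
    s_a: np.ndarray
    df_a: int
    s_w: np.ndarray  # within-cell (replicate) scatter
    df_w: int
    err_coef: float  # coefficient of diag(sigma^2) in Var(contrast)
    individuals: np.ndarray
    fixed: list[str]


def _asymmetry_stats(aligned: AlignedDataset, design=None) -> _AsymmetryStats:
    basis, z = _tangent(aligned)
    df = _merge_design(aligned.keys, design)
    df = df.reset_index(drop=True)
    df["_row"] = np.arange(len(df))
    df["_logcs"] = np.log(aligned.centroid_sizes)

    cell_counts = df.groupby(["specimen_id", "side"]).size()
    if (cell_counts < 2).any():
        bad = cell_counts[cell_counts < 2].index.get_level_values(0).unique()
        raise EstimationError(
            "cannot separate measurement error from developmental variation with a "
            f"single replicate (individuals: {list(bad)[:5]} ...)"
        )
    sides_per_ind = df.groupby("specimen_id")["side"].nunique()
    keep = set(sides_per_ind[sides_per_ind == 2].index)
    dropped = len(sides_per_ind) - len(keep)
    if dropped:
        warnings.warn(f"dropping {dropped} individuals missing one side", stacklevel=2)
    df = df[df["specimen_id"].isin(keep)]
    if df["specimen_id"].nunique() < 3:
        raise EstimationError("too few complete individuals for D estimation")

    # within-cell replicate scatter -> measurement error
    cell = df.groupby(["specimen_id", "side"])
    cell_mean_rows = cell["_row"].apply(list)
    s_w = np.zeros((z.shape[1], z.shape[1]))
    df_w = 0
    cell_means: dict[tuple, np.ndarray] = {}
    for key, rows in cell_mean_rows.items():
        block = z[rows]
        mu = block.mean(axis=0)
        cell_means[key] = mu
        resid = block - mu
        s_w += resid.T @ resid
        df_w += len(rows) - 1

    individuals = np.sort(df["specimen_id"].unique())
    per_ind = df.drop_duplicates("specimen_id").set_index("specimen_id")
    contrasts = np.array(
        [cell_means[(i, "right")] - cell_means[(i, "left")] for i in individuals]
    )
    inv_r = np.array(
        [
            1.0 / cell_counts[(i, "left")] + 1.0 / cell_counts[(i, "right")]
            for i in individuals
        ]
    )
    err_coef = float(inv_r.mean())

    logcs = df.groupby("specimen_id")["_logcs"].mean().loc[individuals].to_numpy()
    x_cols = [np.ones(len(individuals)), logcs - logcs.mean()]
    fixed = ["intercept(directional asymmetry)", "log centroid size"]
    if "cohort" in per_ind.columns and per_ind["cohort"].nunique() > 1:
        x_cols.append(_dummies(per_ind.loc[individuals, "cohort"]))
        fixed.append("cohort")
    x = np.column_stack([np.atleast_2d(c).T if c.ndim == 1 else c for c in x_cols])
    resid, rank = _residualize(contrasts, x)
    s_a = resid.T @ resid
    df_a = len(individuals) - rank
    return _AsymmetryStats(
        basis=basis,
        contrasts_resid=resid,
        s_a=s_a,
        df_a=df_a,
        s_w=s_w,
        df_w=df_w,
        err_coef=err_coef,
        individuals=individuals,
        fixed=fixed,
    )


@dataclass
class _IndividualStats:
    basis: np.ndarray
    resid: np.ndarray  # n_ind x p_t residualized individual mean shapes
    df_resid: int
    individuals: np.ndarray
    n_meas: np.ndarray  # measurements averaged per individual
    fixed: list[str]
    table: pd.DataFrame  # per-individual design rows (aligned subset)


def _individual_stats(
    aligned: AlignedDataset, design=None, extra_terms: bool = True
) -> _IndividualStats:
    basis, z = _tangent(aligned)
    df = _merge_design(aligned.keys, design).reset_index(drop=True)
    df["_logcs"] = np.log(aligned.centroid_sizes)
    individuals = np.sort(df["specimen_id"].unique())
    grouped = df.groupby("specimen_id")
    idx = {ind: rows for ind, rows in grouped.indices.items()}
    means = np.array([z[idx[i]].mean(axis=0) for i in individuals])
    n_meas = np.array([len(idx[i]) for i in individuals], dtype=float)
    logcs = grouped["_logcs"].mean().loc[individuals].to_numpy()
    per_ind = df.drop_duplicates("specimen_id").set_index("specimen_id").loc[individuals]

    x_cols: list[np.ndarray] = [np.ones(len(individuals)), logcs - logcs.mean()]
    fixed = ["intercept", "log centroid size"]
    if extra_terms:
        if "temperature" in per_ind.columns and per_ind["temperature"].nunique() > 1:
            t = per_ind["temperature"].to_numpy(float)
            x_cols.append(t - t.mean())
            fixed.append("temperature")
        if "population_id" in per_ind.columns and per_ind["population_id"].nunique() > 1:
            x_cols.append(_dummies(per_ind["population_id"]))
            fixed.append("population")
        if "cohort" in per_ind.columns and per_ind["cohort"].nunique() > 1:
            x_cols.append(_dummies(per_ind["cohort"]))
            fixed.append("cohort")
    x = np.column_stack([np.atleast_2d(c).T if c.ndim == 1 else c for c in x_cols])
    resid, rank = _residualize(means, x)
    return _IndividualStats(
        basis=basis,
        resid=resid,
        df_resid=len(individuals) - rank,
        individuals=individuals,
        n_meas=n_meas,
        fixed=fixed,
        table=per_ind.reset_index(),
    )


@dataclass
class _FamilyStats:
    s_between: np.ndarray
    df_between: int
    s_within: np.ndarray
    df_within: int
    n0: float  # effective family size
    n_families: int
    n_individuals: int
    families: np.ndarray


def _family_stats(ind: _IndividualStats, design) -> _FamilyStats:
    table = ind.table.set_index("specimen_id")
    if "family_id" not in table.columns:
        raise EstimationError("design table lacks family_id; G is inestimable")
    fam = table.loc[ind.individuals, "family_id"]
    sizes = fam.value_counts()
    usable = sizes[sizes >= 2].index
    if len(usable) == 0:
        raise EstimationError("all families are singletons; G is inestimable")
    mask = fam.isin(usable).to_numpy()
    e = ind.resid[mask]
    fam_codes = np.asarray(pd.Categorical(fam[mask]).codes, dtype=int)
    n_fam = int(fam_codes.max()) + 1
    n = len(e)
    sums = np.zeros((n_fam, e.shape[1]))
    np.add.at(sums, fam_codes, e)
    counts = np.bincount(fam_codes, minlength=n_fam).astype(float)
    fam_means = sums / counts[:, None]
    within = e - fam_means[fam_codes]
    s_w = within.T @ within
    centered = fam_means - e.mean(axis=0)
    s_b = (centered * counts[:, None]).T @ centered
    n0 = (n - (counts**2).sum() / n) / (n_fam - 1)
    # between-family df: families minus between-family fixed-effect dimensions
    fam_table = table.loc[ind.individuals][mask.tolist()]
    n_pops = fam_table["population_id"].nunique() if "population_id" in fam_table else 1
    df_b = n_fam - max(n_pops, 1)
    df_w = n - n_fam - 2  # log centroid size and temperature vary within families
    if df_b < 2 or df_w < 2:
        raise EstimationError("insufficient family structure for G estimation")
    return _FamilyStats(
        s_between=s_b,
        df_between=df_b,
        s_within=s_w,
        df_within=df_w,
        n0=float(n0),
        n_families=int(n_fam),
        n_individuals=n,
        families=np.asarray(pd.Categorical(fam[mask]).categories),
    )


# ---------------------------------------------------------------------------
# REML engine: sums of independent Wishart-type pieces
#
# Each piece contributes -(df log|V| + tr(V^-1 S))/2 with
# V = c_C * C + c_U * U + c_E * diag(s2) + offset,
# C = Lambda Lambda' (+ diag psi), U = Gamma Gamma' (full Cholesky).


@dataclass
class _Piece:
    s: np.ndarray
    df: float
    c_c: float = 0.0
    c_u: float = 0.0
    c_e: float = 0.0
    offset: np.ndarray | None = None


class _REMLProblem:
    def __init__(
        self,
        pieces: list[_Piece],
        p: int,
        m: int,
        include_specific: bool,
        psi_floor: float = 0.0,
    ):
        self.pieces = pieces
        self.p = p
        self.m = m
        self.include_specific = include_specific
        self.psi_floor = psi_floor
        self.has_u = any(pc.c_u for pc in pieces)
        self.has_e = any(pc.c_e for pc in pieces)
        self.lam_idx = np.tril_indices(p, m=m)
        self.n_lam = len(self.lam_idx[0])
        self.gam_idx = np.tril_indices(p)
        self.n_gam = len(self.gam_idx[0]) if self.has_u else 0
        self.n_psi = p if include_specific else 0
        self.n_s2 = p if self.has_e else 0
        self.n_params = self.n_lam + self.n_psi + self.n_gam + self.n_s2

    def pack(self, lam, psi=None, gam=None, s2=None) -> np.ndarray:
        parts = [lam[self.lam_idx]]
        if self.include_specific:
            parts.append(np.log(np.maximum(psi - self.psi_floor, 1e-300)))
        if self.has_u:
            g = gam.copy()
            d = np.arange(self.p)
            g[d, d] = np.log(np.maximum(g[d, d], 1e-300))
            parts.append(g[self.gam_idx])
        if self.has_e:
            parts.append(np.log(np.maximum(s2, 1e-300)))
        return np.concatenate(parts)

    def unpack(self, theta: np.ndarray):
        pos = 0
        lam = np.zeros((self.p, self.m))
        lam[self.lam_idx] = theta[pos : pos + self.n_lam]
        pos += self.n_lam
        psi = None
        if self.include_specific:
            psi = self.psi_floor + np.exp(theta[pos : pos + self.p])
            pos += self.p
        gam = None
        if self.has_u:
            gam = np.zeros((self.p, self.p))
            gam[self.gam_idx] = theta[pos : pos + self.n_gam]
            d = np.arange(self.p)
            gam[d, d] = np.exp(gam[d, d])
            pos += self.n_gam
        s2 = None
        if self.has_e:
            s2 = np.exp(theta[pos : pos + self.p])
        return lam, psi, gam, s2

    def focal(self, theta: np.ndarray) -> np.ndarray:
        lam, psi, _, _ = self.unpack(theta)
        c = lam @ lam.T
        if psi is not None:
            c = c + np.diag(psi)
        return c

    def loglik_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        lam, psi, gam, s2 = self.unpack(theta)
        c = lam @ lam.T
        if psi is not None:
            c = c + np.diag(psi)
        u = gam @ gam.T if gam is not None else None
        ll = 0.0
        g_lam = np.zeros_like(lam)
        g_psi = np.zeros(self.p) if psi is not None else None
        g_gam = np.zeros((self.p, self.p)) if gam is not None else None
        g_s2 = np.zeros(self.p) if s2 is not None else None
        eye = np.eye(self.p)
        for pc in self.pieces:
            v = np.zeros((self.p, self.p))
            if pc.c_c:
                v += pc.c_c * c
            if pc.c_u:
                v += pc.c_u * u
            if pc.c_e:
                v += pc.c_e * np.diag(s2)
            if pc.offset is not None:
                v += pc.offset
            try:
                chol = cho_factor(v, lower=True)
            except np.linalg.LinAlgError:
                return -np.inf, np.zeros(self.n_params)
            v_inv = cho_solve(chol, eye)
            logdet = 2.0 * np.log(np.diag(chol[0])).sum()
            ll += -0.5 * (pc.df * logdet + float(np.sum(v_inv * pc.s)))
            gv = -0.5 * (pc.df * v_inv - v_inv @ pc.s @ v_inv)
            if pc.c_c:
                g_lam += 2.0 * pc.c_c * (gv @ lam)
                if g_psi is not None:
                    g_psi += pc.c_c * np.diag(gv)
            if pc.c_u:
                g_gam += 2.0 * pc.c_u * (gv @ gam)
            if pc.c_e:
                g_s2 += pc.c_e * np.diag(gv)
        parts = [g_lam[self.lam_idx]]
        if psi is not None:
            parts.append(g_psi * (psi - self.psi_floor))  # chain rule for log
        if gam is not None:
            d = np.arange(self.p)
            g_gam[d, d] *= gam[d, d]
            parts.append(g_gam[self.gam_idx])
        if s2 is not None:
            parts.append(g_s2 * s2)
        return ll, np.concatenate(parts)

    @property
    def log_param_mask(self) -> np.ndarray:
        """True for parameters living on a log scale (variance-like)."""
        mask = np.zeros(self.n_params, dtype=bool)
        pos = self.n_lam
        if self.include_specific:
            mask[pos : pos + self.p] = True
            pos += self.p
        if self.has_u:
            # diagonal entries of Gamma are log-parametrized
            diag_cols = self.gam_idx[0] == self.gam_idx[1]
            mask[pos : pos + self.n_gam] = diag_cols
            pos += self.n_gam
        if self.has_e:
            mask[pos : pos + self.p] = True
        return mask

    def fit(
        self,
        theta0: np.ndarray,
        n_starts: int = 3,
        seed: int = 0,
        maxiter: int = 2000,
    ) -> tuple[np.ndarray, float, bool]:
        rng = np.random.default_rng(seed)

        def negobj(theta):
            ll, g = self.loglik_grad(theta)
            if not np.isfinite(ll):
                return 1e30, np.zeros_like(theta)
            return -ll, -g

        # bound log-scale parameters so flat directions cannot drift forever
        bounds = [
            (-35.0, 35.0) if is_log else (None, None) for is_log in self.log_param_mask
        ]
        best = None
        for start in range(max(1, n_starts)):
            theta = np.clip(theta0, -34.0, 34.0)
            if start > 0:
                theta = theta + rng.normal(scale=0.05 * (1 + np.abs(theta)))
            res = minimize(
                negobj,
                theta,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10},
            )
            if not res.success:
                # restart once from the current point; resets L-BFGS memory
                res = minimize(
                    negobj,
                    res.x,
                    jac=True,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10},
                )
            ll = -res.fun
            grad_ok = np.abs(res.jac).max() <= 1e-4 * max(1.0, abs(ll))
            ok = bool(np.isfinite(ll)) and (res.success or grad_ok)
            if best is None or ll > best[1]:
                best = (res.x, ll, ok)
        return best

    def hessian(self, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
        n = len(theta)
        h = np.zeros((n, n))
        for j in range(n):
            step = rel_step * max(1.0, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += step
            tm[j] -= step
            _, gp = self.loglik_grad(tp)
            _, gm = self.loglik_grad(tm)
            h[:, j] = (gp - gm) / (2 * step)
        return 0.5 * (h + h.T)

    def vech_jacobian(self, theta: np.ndarray) -> np.ndarray:
        """d vech(C) / d theta at theta (analytic; zero for U/s2 params)."""
        lam, psi, _, _ = self.unpack(theta)
        pairs = vech_indices(self.p)
        jac = np.zeros((len(pairs), self.n_params))
        for col in range(self.n_lam):
            a, b = self.lam_idx[0][col], self.lam_idx[1][col]
            for row, (i, j) in enumerate(pairs):
                val = 0.0
                if i == a:
                    val += lam[j, b]
                if j == a:
                    val += lam[i, b]
                jac[row, col] = val
        if self.include_specific:
            for a in range(self.p):
                row = pairs.index((a, a))
                jac[row, self.n_lam + a] = psi[a] - self.psi_floor
        return jac


def _lower_triangularize(lam: np.ndarray) -> np.ndarray:
    """Rotate loadings to the lower-triangular identification (LQ form)."""
    m = lam.shape[1]
    if m == 0:
        return lam
    q_mat, _ = np.linalg.qr(lam.T, mode="complete")
    lower = lam @ q_mat[:, :m] if q_mat.shape[1] >= m else lam
    # force non-negative diagonal
    for j in range(min(m, lower.shape[0])):
        if lower[j, j] < 0:
            lower[:, j] = -lower[:, j]
    return np.tril(lower) if lower.shape[0] >= m else lower


def _chol_start(mat: np.ndarray, m: int) -> np.ndarray:
    """Loadings start from the top-m eigenpairs, rotated lower-triangular."""
    sym, _ = nearest_psd(mat)
    vals, vecs = np.linalg.eigh(sym)
    order = np.argsort(vals)[::-1][:m]
    vals = np.clip(vals[order], 1e-12 * max(vals.max(), 1e-300), None)
    lam = vecs[:, order] * np.sqrt(vals)
    lower = np.zeros((mat.shape[0], m))
    lt = _lower_triangularize(lam)
    lower[: lt.shape[0], : lt.shape[1]] = lt[:, :m]
    return lower


# ---------------------------------------------------------------------------
# scaling: optimize in units where variances are O(1)


def _scale_pieces(pieces: list[_Piece]) -> tuple[list[_Piece], float]:
    tot = np.mean([np.trace(pc.s) / (pc.df * pc.s.shape[0]) for pc in pieces])
    scale = max(tot, 1e-300)
    scaled = [
        _Piece(
            s=pc.s / scale,
            df=pc.df,
            c_c=pc.c_c,
            c_u=pc.c_u,
            c_e=pc.c_e,
            offset=None if pc.offset is None else pc.offset / scale,
        )
        for pc in pieces
    ]
    return scaled, scale


def _loglik_offset(pieces: list[_Piece], scale: float) -> float:
    # log-likelihood on the original scale differs by -df*p*log(scale)/2 per piece
    return -0.5 * sum(pc.df * pc.s.shape[0] for pc in pieces) * np.log(scale)


def _fit_reml_full(
    pieces: list[_Piece],
    p: int,
    c_start: np.ndarray,
    u_start: np.ndarray | None = None,
    s2_start: np.ndarray | None = None,
    n_starts: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None, float, bool]:
    """Unstructured (full-rank Cholesky) REML fit; returns (C, U, s2, ll, ok)."""
    scaled, scale = _scale_pieces(pieces)
    prob = _REMLProblem(scaled, p=p, m=p, include_specific=False)
    lam0 = _chol_start(c_start / scale, p)
    gam0 = None
    if prob.has_u:
        u0 = (u_start if u_start is not None else np.eye(p) * np.trace(c_start) / p) / scale
        sym, _ = nearest_psd(u0)
        gam0 = np.linalg.cholesky(sym + 1e-8 * np.trace(sym + np.eye(p)) / p * np.eye(p))
    s2_0 = None
    if prob.has_e:
        s2_0 = (s2_start if s2_start is not None else np.full(p, np.trace(c_start) / p)) / scale
        s2_0 = np.maximum(s2_0, 1e-12)
    theta0 = prob.pack(lam0, gam=gam0, s2=s2_0)
    theta, ll, ok = prob.fit(theta0, n_starts=n_starts, seed=seed)
    lam, _, gam, s2 = prob.unpack(theta)
    c_hat = lam @ lam.T * scale
    u_hat = gam @ gam.T * scale if gam is not None else None
    s2_hat = s2 * scale if s2 is not None else None
    return c_hat, u_hat, s2_hat, ll + _loglik_offset(pieces, scale), ok


# ---------------------------------------------------------------------------
# the three matrices


def _embed(basis: np.ndarray, c: np.ndarray) -> np.ndarray:
    return basis @ c @ basis.T


def estimate_D(
    aligned: AlignedDataset,
    design=None,
    method: str = "moment",
    clip: bool = True,
    compute_sampling_cov: bool = True,
) -> CovarianceMatrix:
    """Developmental covariance from the individual x side interaction.

    Signed right-minus-left contrasts of replicate-mean shapes (centered to
    remove directional asymmetry, residualized on log centroid size and, when
    present, cohort) estimate 2 D + c diag(sigma^2); the measurement-error
    variances come from replicate differences within each (individual, side)
    cell. method='moment' uses the closed-form ANOVA estimator, method='reml'
    maximizes the joint Wishart restricted likelihood of both statistics.
    Individuals are pooled across populations and treatments.
    """
    st = _asymmetry_stats(aligned, design)
    pt = st.s_a.shape[1]
    s2_hat = np.diag(st.s_w) / st.df_w
    v_a = st.s_a / st.df_a
    if method == "moment":
        d_red = 0.5 * (v_a - st.err_coef * np.diag(s2_hat))
        ll = np.nan
    elif method == "reml":
        d_start = 0.5 * (v_a - st.err_coef * np.diag(s2_hat))
        d_start, _ = nearest_psd(d_start)
        pieces = [
            _Piece(s=st.s_a, df=st.df_a, c_c=2.0, c_e=st.err_coef),
            _Piece(s=st.s_w, df=st.df_w, c_e=1.0),
        ]
        d_red, _, s2_hat, ll, ok = _fit_reml_full(
            pieces, pt, c_start=d_start, s2_start=s2_hat
        )
        if not ok:
            raise EstimationError("REML for D did not converge")
    else:
        raise ValueError(f"unknown method {method!r}")
    clipped = False
    if clip:
        d_red, clipped = nearest_psd(d_red)
    sampling_cov = None
    if compute_sampling_cov:
        sampling_cov = 0.25 * wishart_vech_cov(v_a, st.df_a)
        # add the (diagonal-only) uncertainty of the measurement-error correction
        pairs = vech_indices(pt)
        for idx, (i, j) in enumerate(pairs):
            if i == j:
                sampling_cov[idx, idx] += (st.err_coef / 2) ** 2 * 2 * s2_hat[i] ** 2 / st.df_w
    return CovarianceMatrix(
        label="D",
        values=_embed(st.basis, d_red),
        selected_rank=effective_rank(d_red),
        fixed_effects_adjusted_for=st.fixed,
        n_units=len(st.individuals),
        basis=st.basis,
        reduced=d_red,
        sampling_cov=sampling_cov,
        meas_variances=s2_hat,
        method=method,
    )


def estimate_P(
    aligned: AlignedDataset,
    design=None,
    method: str = "moment",
    clip: bool = True,
    compute_sampling_cov: bool = True,
) -> CovarianceMatrix:
    """Among-individual (phenotypic) covariance after fixed-effect adjustment.

    Individual mean shapes (side- and replicate-averaged) are residualized on
    log centroid size, temperature, population and cohort; the developmental
    and measurement components their averaging leaves behind are subtracted
    using the D and error estimates.
    """
    ind = _individual_stats(aligned, design, extra_terms=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # unclipped internal D may be indefinite
        d_fit = estimate_D(aligned, design, method="moment", clip=False,
                           compute_sampling_cov=compute_sampling_cov)
    pt = ind.resid.shape[1]
    s_p = ind.resid.T @ ind.resid
    v_p = s_p / ind.df_resid
    n_sides = 2.0
    mean_inv_meas = float((1.0 / ind.n_meas).mean())
    offset_red = d_fit.reduced / n_sides + mean_inv_meas * np.diag(d_fit.meas_variances)
    if method == "moment":
        p_red = v_p - offset_red
    elif method == "reml":
        start, _ = nearest_psd(v_p - offset_red)
        off_psd, _ = nearest_psd(offset_red)
        pieces = [_Piece(s=s_p, df=ind.df_resid, c_c=1.0, offset=off_psd)]
        p_red, _, _, ll, ok = _fit_reml_full(pieces, pt, c_start=start)
        if not ok:
            raise EstimationError("REML for P did not converge")
    else:
        raise ValueError(f"unknown method {method!r}")
    clipped = False
    if clip:
        p_red, clipped = nearest_psd(p_red)
    sampling_cov = None
    if compute_sampling_cov:
        # Individual means are clustered within families, so the naive
        # Wishart(df_resid) covariance of V_p overstates precision; split the
        # scatter into between- and within-family Wishart pieces instead.
        fam = None
        if design is not None and "family_id" in ind.table.columns:
            fam = ind.table.set_index("specimen_id").loc[ind.individuals, "family_id"]
        if fam is not None and fam.notna().all() and fam.nunique() < len(ind.individuals):
            codes = np.asarray(pd.Categorical(fam).codes, dtype=int)
            n_fam = int(codes.max()) + 1
            sums = np.zeros((n_fam, ind.resid.shape[1]))
            np.add.at(sums, codes, ind.resid)
            counts = np.bincount(codes, minlength=n_fam).astype(float)
            fam_means = sums / counts[:, None]
            w_scatter = (ind.resid - fam_means[codes]).T @ (ind.resid - fam_means[codes])
            df_w = max(len(ind.individuals) - n_fam, 2)
            df_tot = ind.df_resid
            cov_scatter = df_w**2 * wishart_vech_cov(w_scatter / df_w, df_w)
            # family means of different sizes have different covariances
            # (n_f G + U scaled); treat each size class as its own Wishart
            rank_b = max(len(ind.fixed) - 2, 1)  # between-family fixed effects
            for size in np.unique(counts):
                in_class = counts == size
                f_c = int(in_class.sum())
                df_c = max(f_c - rank_b * f_c / n_fam, 1.5)
                means_c = fam_means[in_class]
                s_c = size * (means_c.T @ means_c)
                cov_scatter += df_c**2 * wishart_vech_cov(s_c / df_c, df_c)
            sampling_cov = cov_scatter / df_tot**2
        else:
            sampling_cov = wishart_vech_cov(v_p, ind.df_resid)
        if d_fit.sampling_cov is not None:
            sampling_cov = sampling_cov + d_fit.sampling_cov / n_sides**2
    return CovarianceMatrix(
        label="P",
        values=_embed(ind.basis, p_red),
        selected_rank=effective_rank(p_red),
        fixed_effects_adjusted_for=ind.fixed,
        n_units=len(ind.individuals),
        basis=ind.basis,
        reduced=p_red,
        sampling_cov=sampling_cov,
        meas_variances=d_fit.meas_variances,
        method=method,
    )


def estimate_G(
    aligned: AlignedDataset,
    design=None,
    method: str = "moment",
    clip: bool = True,
    compute_sampling_cov: bool = True,
) -> CovarianceMatrix:
    """Broad-sense genetic covariance from the between-family component.

    Individual mean shapes are residualized on log centroid size, temperature
    and population; the between/within full-sib family decomposition gives
    G as (MS_between - MS_within) / n0. Families with a single offspring are
    dropped. The estimate pools within-population genetic covariation and
    includes non-additive (full-sib) components.
    """
    ind = _individual_stats(aligned, design, extra_terms=True)
    fam = _family_stats(ind, design)
    pt = ind.resid.shape[1]
    v_b = fam.s_between / fam.df_between
    v_w = fam.s_within / fam.df_within
    if method == "moment":
        g_red = (v_b - v_w) / fam.n0
    elif method == "reml":
        start, _ = nearest_psd((v_b - v_w) / fam.n0)
        pieces = [
            _Piece(s=fam.s_between, df=fam.df_between, c_c=fam.n0, c_u=1.0),
            _Piece(s=fam.s_within, df=fam.df_within, c_u=1.0),
        ]
        g_red, _, _, ll, ok = _fit_reml_full(pieces, pt, c_start=start, u_start=v_w)
        if not ok:
            raise EstimationError("REML for G did not converge")
    else:
        raise ValueError(f"unknown method {method!r}")
    clipped = False
    if clip:
        g_red, clipped = nearest_psd(g_red)
    sampling_cov = None
    if compute_sampling_cov:
        sampling_cov = (
            wishart_vech_cov(v_b, fam.df_between) + wishart_vech_cov(v_w, fam.df_within)
        ) / fam.n0**2
    return CovarianceMatrix(
        label="G",
        values=_embed(ind.basis, g_red),
        selected_rank=effective_rank(g_red),
        fixed_effects_adjusted_for=ind.fixed,
        n_units=fam.n_families,
        basis=ind.basis,
        reduced=g_red,
        sampling_cov=sampling_cov,
        method=method,
    )


def estimate_dgp(
    aligned: AlignedDataset,
    design=None,
    method: str = "moment",
    compute_sampling_cov: bool = True,
) -> dict[str, CovarianceMatrix]:
    """Convenience: estimate D, G and P from the same aligned dataset."""
    kw = {"method": method, "compute_sampling_cov": compute_sampling_cov}
    return {
        "D": estimate_D(aligned, design, **kw),
        "G": estimate_G(aligned, design, **kw),
        "P": estimate_P(aligned, design, **kw),
    }


def resample_dgp(
    aligned: AlignedDataset,
    design,
    n_samples: int,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Joint REML-MVN draws of (D, G, P) from shared sufficient statistics.

    The three estimators are functions of a common set of scatter matrices
    (asymmetry contrasts, within-cell replicate scatter, between- and
    within-family scatters), so their sampling errors are correlated — P and
    G in particular share the between-family information. Per-matrix
    independent resampling ignores this; here each draw samples the scatter
    matrices once from their Wishart-normal approximations and rebuilds all
    three estimates, preserving the correlation structure. Returns arrays of
    shape (n_samples, p, p) per label; non-PSD reconstructions are clipped.
    """
    ast = _asymmetry_stats(aligned, design)
    ind = _individual_stats(aligned, design, extra_terms=True)
    basis = ind.basis
    pt = ind.resid.shape[1]
    rng = np.random.default_rng(seed)

    # family grouping over all individuals (singletons form their own class)
    table = ind.table.set_index("specimen_id")
    if "family_id" not in table.columns:
        raise EstimationError("joint resampling requires family structure")
    fam = table.loc[ind.individuals, "family_id"]
    codes = np.asarray(pd.Categorical(fam).codes, dtype=int)
    n_fam = int(codes.max()) + 1
    sums = np.zeros((n_fam, pt))
    np.add.at(sums, codes, ind.resid)
    counts = np.bincount(codes, minlength=n_fam).astype(float)
    fam_means = sums / counts[:, None]
    within = ind.resid - fam_means[codes]
    s_w = within.T @ within
    df_w = max(len(ind.individuals) - n_fam, 2)
    v_w = s_w / df_w

    multi = counts >= 2
    if not multi.any():
        raise EstimationError("all families are singletons; joint resampling undefined")
    n_pops = table["population_id"].nunique() if "population_id" in table else 1
    rank_b = max(n_pops, 1)
    classes = []
    for size in np.unique(counts):
        in_class = counts == size
        f_c = int(in_class.sum())
        df_c = max(f_c - rank_b * f_c / n_fam, 1.5)
        means_c = fam_means[in_class]
        classes.append(
            {
                "size": size,
                "df": df_c,
                "v": size * (means_c.T @ means_c) / df_c,
                "multi": size >= 2,
            }
        )
    df_total = ind.df_resid
    n_eff = counts[multi]
    n0 = float(
        (n_eff.sum() - (n_eff**2).sum() / n_eff.sum()) / max(multi.sum() - 1, 1)
    )
    v_a = ast.s_a / ast.df_a
    s2 = np.diag(ast.s_w) / ast.df_w
    n_meas_inv = float((1.0 / ind.n_meas).mean())

    def vech_normal_draws(v_mat, df, n):
        cov = wishart_vech_cov(v_mat, df)
        vals, vecs = np.linalg.eigh(0.5 * (cov + cov.T))
        root = vecs * np.sqrt(np.clip(vals, 0.0, None))
        z = rng.standard_normal((n, len(vech(v_mat))))
        return vech(v_mat) + z @ root.T

    draws_a = vech_normal_draws(v_a, ast.df_a, n_samples)
    draws_s2 = s2 + rng.standard_normal((n_samples, pt)) * np.sqrt(
        2.0 * s2**2 / ast.df_w
    )
    draws_s2 = np.clip(draws_s2, 0.0, None)
    draws_w = vech_normal_draws(v_w, df_w, n_samples)
    class_draws = [vech_normal_draws(c["v"], c["df"], n_samples) for c in classes]

    out = {lbl: np.empty((n_samples, basis.shape[0], basis.shape[0])) for lbl in "DGP"}
    multi_class = [i for i, c in enumerate(classes) if c["multi"]]
    for i in range(n_samples):
        w_i = unvech(draws_w[i], pt)
        d_i, _ = nearest_psd(0.5 * (unvech(draws_a[i], pt) - ast.err_coef * np.diag(draws_s2[i])))
        # between-family component: pool multi-offspring classes
        b_multi = sum(classes[j]["df"] * unvech(class_draws[j][i], pt) for j in multi_class)
        df_multi = sum(classes[j]["df"] for j in multi_class)
        g_i, _ = nearest_psd((b_multi / df_multi - w_i) / n0)
        v_p_i = (
            sum(classes[j]["df"] * unvech(class_draws[j][i], pt) for j in range(len(classes)))
            + df_w * w_i
        ) / df_total
        p_i, _ = nearest_psd(
            v_p_i - d_i / 2.0 - n_meas_inv * np.diag(draws_s2[i])
        )
        out["D"][i] = basis @ d_i @ basis.T
        out["G"][i] = basis @ g_i @ basis.T
        out["P"][i] = basis @ p_i @ basis.T
    return out


def jackknife_dgp(
    aligned: AlignedDataset,
    design,
    statistic: Callable[[dict[str, CovarianceMatrix]], float],
    unit: str = "family",
) -> np.ndarray:
    """Leave-one-unit-out values of a statistic of the (D, G, P) estimates.

    ``unit='family'`` drops one family (all its individuals) at a time, the
    appropriate resolution for the genetic component; used for the BCa
    acceleration constant.
    """
    keys = aligned.keys
    merged = _merge_design(keys, design)
    if unit == "family":
        groups = merged["family_id"].fillna("__none__")
    elif unit == "individual":
        groups = merged["specimen_id"]
    else:
        raise ValueError(f"unknown jackknife unit {unit!r}")
    labels = pd.unique(groups)
    values = []
    for lab in labels:
        mask = (groups != lab).to_numpy()
        sub = AlignedDataset(
            shape_coords=aligned.shape_coords[mask],
            centroid_sizes=aligned.centroid_sizes[mask],
            consensus=aligned.consensus,
            keys=keys.loc[mask].reset_index(drop=True),
            n_iterations=aligned.n_iterations,
            final_change=aligned.final_change,
            reflect_side=aligned.reflect_side,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                values.append(
                    statistic(estimate_dgp(sub, design, compute_sampling_cov=False))
                )
            except EstimationError:
                continue
    return np.asarray(values)


# ---------------------------------------------------------------------------
# reduced-rank (factor-analytic) fits


def _pieces_for_structure(
    aligned: AlignedDataset, design, random_structure: str
) -> tuple[list[_Piece], np.ndarray, np.ndarray, np.ndarray | None, int, str]:
    """(pieces, basis, C_start, s2_start, n_units, label) for a random term."""
    if random_structure in ("individual_by_side", "D"):
        st = _asymmetry_stats(aligned, design)
        s2 = np.diag(st.s_w) / st.df_w
        c0, _ = nearest_psd(0.5 * (st.s_a / st.df_a - st.err_coef * np.diag(s2)))
        pieces = [
            _Piece(s=st.s_a, df=st.df_a, c_c=2.0, c_e=st.err_coef),
            _Piece(s=st.s_w, df=st.df_w, c_e=1.0),
        ]
        return pieces, st.basis, c0, s2, len(st.individuals), "D"
    if random_structure in ("family", "G"):
        ind = _individual_stats(aligned, design, extra_terms=True)
        fam = _family_stats(ind, design)
        v_w = fam.s_within / fam.df_within
        c0, _ = nearest_psd((fam.s_between / fam.df_between - v_w) / fam.n0)
        pieces = [
            _Piece(s=fam.s_between, df=fam.df_between, c_c=fam.n0, c_u=1.0),
            _Piece(s=fam.s_within, df=fam.df_within, c_u=1.0),
        ]
        return pieces, ind.basis, c0, None, fam.n_families, "G"
    raise ValueError(f"unknown random_structure {random_structure!r}")


def fit_factor_model(
    aligned: AlignedDataset,
    design,
    m: int,
    random_structure: str = "individual_by_side",
    include_specific: bool = True,
    n_starts: int = 3,
    seed: int = 0,
    compute_sampling_cov: bool = False,
) -> FactorModel:
    """Fit a rank-m factor-analytic covariance model by REML.

    The focal covariance is parameterized as Lambda Lambda' + diag(psi) with
    lower-triangular Lambda (non-negative diagonal) and psi >= a small floor.
    Residual (measurement-level) variances are estimated per tangent
    coordinate where the structure involves them. Non-convergence is flagged
    on the returned model, never silent.
    """
    pieces, basis, c0, s2_0, n_units, label = _pieces_for_structure(
        aligned, design, random_structure
    )
    pt = c0.shape[0]
    if not 1 <= m <= pt:
        raise ValueError(f"m must be in [1, {pt}]")
    scaled, scale = _scale_pieces(pieces)
    floor = 1e-10 * max(np.trace(c0) / scale, 1e-12)
    prob = _REMLProblem(scaled, p=pt, m=m, include_specific=include_specific,
                        psi_floor=floor)
    lam0 = _chol_start(c0 / scale, m)
    resid0 = np.maximum(np.diag(c0 / scale) - np.sum(lam0**2, axis=1), 1e-8)
    psi0 = resid0 if include_specific else None
    gam0 = None
    if prob.has_u:
        v_w = pieces[1].s / pieces[1].df / scale
        sym, _ = nearest_psd(v_w)
        gam0 = np.linalg.cholesky(sym + 1e-8 * np.eye(pt))
    s2_scaled = np.maximum(s2_0 / scale, 1e-12) if s2_0 is not None else None
    theta0 = prob.pack(lam0, psi=psi0, gam=gam0, s2=s2_scaled)
    theta, ll, ok = prob.fit(theta0, n_starts=n_starts, seed=seed)
    lam, psi, gam, s2 = prob.unpack(theta)
    lam = _lower_triangularize(lam * np.sqrt(scale))
    psi_out = (psi - floor) * scale if psi is not None else np.zeros(pt)
    s2_out = s2 * scale if s2 is not None else None
    param_cov = vech_cov = None
    if compute_sampling_cov:
        h = prob.hessian(theta)
        info = -h
        param_cov = np.linalg.pinv(info)
        jac = prob.vech_jacobian(theta)
        vech_cov = (jac @ param_cov @ jac.T) * scale**2
    return FactorModel(
        loadings=lam,
        specific_variances=psi_out,
        residual_variances=s2_out,
        loglik=ll + _loglik_offset(pieces, scale),
        n_params=prob.n_params,
        converged=ok,
        basis=basis,
        structure=random_structure,
        label=label,
        n_units=n_units,
        param_sampling_cov=param_cov,
        vech_sampling_cov=vech_cov,
    )


def select_rank(
    aligned: AlignedDataset,
    design,
    m_max: int,
    random_structure: str = "individual_by_side",
    include_specific: bool = True,
    n_starts: int = 3,
    seed: int = 0,
) -> tuple[int, pd.DataFrame, dict[int, FactorModel]]:
    """AIC-based dimensionality selection of a factor-analytic covariance.

    Fits m = 1, 2, ... and stops early once AIC increases over the previous
    converged fit or a fit fails to converge; returns the AIC-minimizing m
    among converged fits, the full AIC trace, and the fitted models.
    """
    rows = []
    models: dict[int, FactorModel] = {}
    best_aic = np.inf
    prev_aic = np.inf
    for m in range(1, m_max + 1):
        fit = fit_factor_model(
            aligned,
            design,
            m,
            random_structure=random_structure,
            include_specific=include_specific,
            n_starts=n_starts,
            seed=seed + m,
        )
        rows.append(
            {
                "m": m,
                "loglik": fit.loglik,
                "n_params": fit.n_params,
                "aic": fit.aic,
                "converged": fit.converged,
            }
        )
        if fit.converged:
            models[m] = fit
            if fit.aic < best_aic:
                best_aic = fit.aic
            if fit.aic > prev_aic:
                break
            prev_aic = fit.aic
        else:
            break
    table = pd.DataFrame(rows)
    converged = table[table["converged"]]
    if converged.empty:
        raise EstimationError("no factor-analytic fit converged")
    m_star = int(converged.loc[converged["aic"].idxmin(), "m"])
    return m_star, table, models


def reconstruct_cov(model: FactorModel, include_specific: bool = True) -> CovarianceMatrix:
    """Covariance matrix implied by a factor model: Lambda Lambda' (+ diag psi).

    ``include_specific=True`` (default) returns the full implied covariance;
    set False for the common (rank-m) part only.
    """
    if not model.converged:
        raise EstimationError("refusing to reconstruct from a non-converged model")
    c = model.implied_reduced(include_specific=include_specific)
    c, _ = nearest_psd(c)
    return CovarianceMatrix(
        label=model.label,
        values=_embed(model.basis, c),
        selected_rank=model.m,
        fixed_effects_adjusted_for=[],
        n_units=model.n_units,
        basis=model.basis,
        reduced=c,
        sampling_cov=model.vech_sampling_cov,
        method=f"fa(m={model.m})",
    )
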