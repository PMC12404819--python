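"""Synthetic bilateral landmark datasets with known covariance structure.

The generator reads the variance-component model generatively: for individual
i (of family f), side s and replicate r,

    shape_{i,s,r} = mu + allometry * (logCS_i - mean)
                  + beta_T * 1[temp_i = high] + beta_L * (lat_i - mean lat)
                  + DA * 1[s = right]
                  + g_f + e_i + d_{i,s} + eps_{i,s,r}

with g ~ N(0, G), e ~ N(0, E), d ~ N(0, D) and eps ~ N(0, diag(sigma_meas^2)).
All systematic deviations live in the (2k - 4)-dimensional tangent space of the
mean shape, so the true covariance matrices occupy the same space as Procrustes
estimates. Raw outputs are produced as a camera would record them: the left
side is mirrored, and every record receives an independent random rotation,
translation and scale so that Procrustes alignment is non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._geometry import normalize, project_to_tangent, tangent_basis
from .io import DesignTable, LandmarkConfiguration

__all__ = [
    "SimulationParams",
    "TruthRecord",
    "simulate_dataset",
    "default_paper_design",
    "calibration_design",
]


class ParameterError(ValueError):
    """Invalid simulation parameters (non-PSD matrix, dimension mismatch)."""


# A slightly irregular octagon standing in for a digitized tibia outline.
_DEFAULT_MEAN_SHAPE = np.array(
    [
        [1.20, 0.00],
        [0.80, 0.55],
        [0.20, 0.75],
        [-0.50, 0.70],
        [-1.10, 0.45],
        [-1.20, -0.20],
        [-0.40, -0.60],
        [0.60, -0.45],
    ]
)


@dataclass
class SimulationParams:
    n_families: int
    offspring_per_family: int
    populations: list[tuple[str, float]]  # (id, latitude)
    temperatures: list[float]
    k_landmarks: int
    mean_shape: np.ndarray  # (k, 2)
    G_true: np.ndarray  # p x p
    E_true: np.ndarray  # p x p, individual-environment deviations
    D_true: np.ndarray  # p x p, side-specific developmental noise
    sigma_meas: np.ndarray  # p-vector of measurement-error SDs
    DA_vector: np.ndarray  # p-vector, directional asymmetry (added to right side)
    allometry_vector: np.ndarray  # p-vector per unit log centroid size
    beta_latitude: np.ndarray  # p-vector per degree latitude
    beta_temperature: np.ndarray  # p-vector per temperature contrast (low -> high)
    size_distribution: tuple[float, float]  # (mean, SD) of log centroid size
    n_replicates: int = 2
    n_extra_individuals: int = 0  # unstructured lab cohort (singleton families)
    extra_population: str | None = None
    nuisance: dict | None = field(
        default_factory=lambda: {
            "rotation": (-np.pi, np.pi),
            "translation": (-200.0, 200.0),
            "scale": (0.95, 1.05),
        }
    )
    seed: int = 0

    @property
    def p(self) -> int:
        return 2 * self.k_landmarks

    @property
    def n_individuals(self) -> int:
        return self.n_families * self.offspring_per_family + self.n_extra_individuals

    def validate(self) -> None:
        p = self.p
        for name in ("G_true", "E_true", "D_true"):
            mat = np.asarray(getattr(self, name), dtype=float)
            if mat.shape != (p, p):
                raise ParameterError(f"{name} must be {p}x{p}, got {mat.shape}")
            if not np.allclose(mat, mat.T, atol=1e-10):
                raise ParameterError(f"{name} is not symmetric")
            vals = np.linalg.eigvalsh(mat)
            tr = max(np.trace(mat), np.finfo(float).tiny)
            if vals.min() < -1e-8 * tr:
                raise ParameterError(f"{name} is not positive semidefinite")
        for name in ("sigma_meas", "DA_vector", "allometry_vector", "beta_latitude",
                     "beta_temperature"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (p,):
                raise ParameterError(f"{name} must be a length-{p} vector, got {v.shape}")
        if np.asarray(self.mean_shape).shape != (self.k_landmarks, 2):
            raise ParameterError("mean_shape must be (k_landmarks, 2)")
        if (np.asarray(self.sigma_meas) < 0).any():
            raise ParameterError("sigma_meas must be non-negative")
        if not self.temperatures:
            raise ParameterError("at least one rearing temperature is required")

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=int(seed))


@dataclass
class TruthRecord:
    """Realized deviations and input matrices, for parameter-recovery tests."""

    params: SimulationParams
    basis: np.ndarray  # p x (p-4) tangent basis at the mean shape
    family_effects: pd.DataFrame  # family_id x p (embedded)
    individual_effects: pd.DataFrame  # specimen_id x p
    side_effects: pd.DataFrame  # (specimen_id, side) x p
    G_true: np.ndarray
    E_true: np.ndarray
    D_true: np.ndarray
    P_true: np.ndarray  # G + E
    log_centroid_sizes: pd.Series

    @property
    def dmax(self) -> np.ndarray:
        vals, vecs = np.linalg.eigh(self.D_true)
        return vecs[:, -1]

    @property
    def gmax(self) -> np.ndarray:
        vals, vecs = np.linalg.eigh(self.G_true)
        return vecs[:, -1]

    def eigen(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        mat = {"G": self.G_true, "D": self.D_true, "P": self.P_true}[which]
        vals, vecs = np.linalg.eigh(mat)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def simulate_dataset(
    params: SimulationParams,
) -> tuple[list[LandmarkConfiguration], DesignTable, TruthRecord]:
    """Generate a full bilateral dataset.

    Returns raw (unaligned) configurations, the design table, and a
    TruthRecord with the realized random effects so downstream estimates can
    be checked against ground truth. All randomness is a pure function of
    ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    mean = normalize(np.asarray(params.mean_shape, dtype=float))
    basis = tangent_basis(mean)
    mean_flat = mean.reshape(-1)
    p = params.p

    # Systematic inputs projected into the tangent space so truth and
    # Procrustes estimates live in the same (2k - 4)-dimensional space.
    G_t = project_to_tangent(np.asarray(params.G_true, float), basis)
    E_t = project_to_tangent(np.asarray(params.E_true, float), basis)
    D_t = project_to_tangent(np.asarray(params.D_true, float), basis)
    da = project_to_tangent(np.asarray(params.DA_vector, float), basis)
    allo = project_to_tangent(np.asarray(params.allometry_vector, float), basis)
    b_lat = project_to_tangent(np.asarray(params.beta_latitude, float), basis)
    b_temp = project_to_tangent(np.asarray(params.beta_temperature, float), basis)

    def draw(cov: np.ndarray, n: int) -> np.ndarray:
        vals, vecs = np.linalg.eigh(cov)
        vals = np.clip(vals, 0.0, None)
        z = rng.standard_normal((n, p))
        return z @ (vecs * np.sqrt(vals)).T

    # --- design layout -----------------------------------------------------
    pops = list(params.populations)
    temps = sorted(params.temperatures)
    high_temp = temps[-1]
    rows = []
    fam_of: list[str] = []
    for f in range(params.n_families):
        pop_id, lat = pops[f % len(pops)]
        fam = f"F{f + 1:03d}"
        fam_of.append(fam)
        for o in range(params.offspring_per_family):
            temp = temps[o % len(temps)]  # brood split evenly across temperatures
            rows.append(
                {
                    "specimen_id": f"{fam}_{o + 1}",
                    "family_id": fam,
                    "population_id": pop_id,
                    "latitude": lat,
                    "temperature": temp,
                    "cohort": "common_garden",
                }
            )
    extra_pop = params.extra_population or (pops[0][0] if pops else "X")
    extra_lat = dict(pops).get(extra_pop, np.nan)
    for j in range(params.n_extra_individuals):
        fam = f"X{j + 1:03d}"
        fam_of.append(fam)
        rows.append(
            {
                "specimen_id": f"{fam}_1",
                "family_id": fam,
                "population_id": extra_pop,
                "latitude": extra_lat,
                "temperature": temps[j % len(temps)],
                "cohort": "lab",
            }
        )
    design_df = pd.DataFrame(rows)
    n_ind = len(design_df)

    # --- random effects ----------------------------------------------------
    families = design_df["family_id"].unique()
    g = draw(G_t, len(families))
    g_by_fam = dict(zip(families, g))
    e = draw(E_t, n_ind)
    log_cs = rng.normal(params.size_distribution[0], params.size_distribution[1], n_ind)
    mean_log_cs = params.size_distribution[0]
    lat_vals = design_df["latitude"].to_numpy(dtype=float)
    mean_lat = np.nanmean(lat_vals)
    lat_centered = np.where(np.isnan(lat_vals), 0.0, lat_vals - mean_lat)

    configs: list[LandmarkConfiguration] = []
    side_rows = []
    ind_rows = []
    nuis = params.nuisance
    for i, row in design_df.iterrows():
        fixed = (
            allo * (log_cs[i] - mean_log_cs)
            + b_temp * float(row["temperature"] == high_temp)
            + b_lat * lat_centered[i]
        )
        ind_dev = g_by_fam[row["family_id"]] + e[i]
        ind_rows.append(ind_dev)
        cs = float(np.exp(log_cs[i]))
        for side in ("left", "right"):
            d = draw(D_t, 1)[0]
            side_rows.append({"specimen_id": row["specimen_id"], "side": side, "effect": d})
            base = mean_flat + fixed + ind_dev + d + (da if side == "right" else 0.0)
            for rep in range(1, params.n_replicates + 1):
                eps = rng.standard_normal(p) * np.asarray(params.sigma_meas, float)
                coords = (base + eps).reshape(-1, 2) * cs
                if side == "left":
                    coords = coords * np.array([-1.0, 1.0])  # as the camera sees it
                if nuis is not None:
                    theta = rng.uniform(*nuis["rotation"])
                    scale = rng.uniform(*nuis["scale"])
                    shift = rng.uniform(*nuis["translation"], size=2)
                    coords = scale * coords @ _rot(theta).T + shift
                configs.append(
                    LandmarkConfiguration(
                        specimen_id=row["specimen_id"],
                        side=side,
                        replicate=rep,
                        coords=coords,
                        metadata={
                            "family_id": row["family_id"],
                            "population_id": row["population_id"],
                        },
                    )
                )

    design = DesignTable(design_df)
    fam_df = pd.DataFrame(
        [g_by_fam[f] for f in families], index=pd.Index(families, name="family_id")
    )
    ind_df = pd.DataFrame(
        np.asarray(ind_rows), index=pd.Index(design_df["specimen_id"], name="specimen_id")
    )
    side_df = pd.DataFrame(
        [r["effect"] for r in side_rows],
        index=pd.MultiIndex.from_tuples(
            [(r["specimen_id"], r["side"]) for r in side_rows], names=["specimen_id", "side"]
        ),
    )
    truth = TruthRecord(
        params=params,
        basis=basis,
        family_effects=fam_df,
        individual_effects=ind_df,
        side_effects=side_df,
        G_true=G_t,
        E_true=E_t,
        D_true=D_t,
        P_true=G_t + E_t,
        log_centroid_sizes=pd.Series(log_cs, index=design_df["specimen_id"]),
    )
    return configs, design, truth


# ---------------------------------------------------------------------------
# default parameter sets


def _orthonormal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def _embed(basis: np.ndarray, c: np.ndarray) -> np.ndarray:
    return basis @ c @ basis.T


def _vector_with_target_eval(
    rng: np.random.Generator,
    basis: np.ndarray,
    q_cols: np.ndarray,
    eigvals_frac: np.ndarray,
    target: float,
) -> np.ndarray:
    """Unit p-vector orthogonal to the leading eigenvector of D with a
    prescribed value of the trace-scaled quadratic form (the e_beta statistic).

    Built as cos(t)*u0 + sin(t)*u1 with u0 in the null space of D and u1 in
    the span of eigenvectors 2..4; because D u0 = 0 the quadratic form equals
    sin(t)^2 * (u1' D u1), so t solves for the target exactly.
    """
    t_dim = basis.shape[1]
    rank = len(eigvals_frac)
    # random unit vector in D's null space (tangent coordinates)
    z0 = rng.standard_normal(t_dim - rank)
    u0 = q_cols[:, rank:] @ (z0 / np.linalg.norm(z0))
    # random unit vector in span of eigenvectors 2..4 (skipping dmax)
    z1 = rng.standard_normal(3)
    z1 /= np.linalg.norm(z1)
    u1 = q_cols[:, 1:4] @ z1
    e1 = float(z1**2 @ eigvals_frac[1:4])
    if e1 < target:
        raise ValueError("cannot reach target alignment from this span")
    t = np.arcsin(np.sqrt(target / e1))
    u = np.cos(t) * u0 + np.sin(t) * u1
    return basis @ u


def default_paper_design(seed: int = 0) -> SimulationParams:
    """Parameter set emulating the published common-garden study design.

    434 individuals (54 full-sib families x 6 offspring reared in a common
    garden, split evenly across 19/27 deg C, plus 110 unstructured
    laboratory-reared individuals), 5 populations with a latitudinal spread,
    8 landmarks (16 shape variables), 2 sides x 2 replicate measurements.
    D_true has rank 7 and G_true rank 6; each genetic eigenvector is its
    developmental counterpart rotated by 41.5 degrees toward an orthogonal
    direction (gmax-dmax vector correlation 0.75), with genetic log-variances
    related to the developmental ones with slope 2 on the paired axes — a
    partial developmental-genetic alignment. The thermal-plasticity and
    latitudinal shape-change vectors are orthogonal to dmax and capture a
    small fixed fraction of developmental variance (0.087 and 0.076 of the
    trace-scaled D). Variance scales are set so the expected Goodall F of the
    fluctuating-asymmetry term is ~4.7 and FA accounts for ~11% of total
    shape variance.

    ``seed`` controls only the data-generating stream; the true matrices are
    built from a fixed internal stream, so truth is identical across seeds.
    """
    k = 8
    mean = normalize(_DEFAULT_MEAN_SHAPE)
    basis = tangent_basis(mean)
    t_dim = basis.shape[1]  # 12
    build_rng = np.random.default_rng(20250903)

    q = _orthonormal(build_rng, t_dim)
    d_frac = 0.65 ** np.arange(7)
    d_frac /= d_frac.sum()
    # Expected within-cell (measurement) trace in shape space: sigma^2 * t_dim.
    sigma_meas = 0.0025
    m_t = sigma_meas**2 * t_dim
    trace_d = (4.71 - 1.0) * m_t / 2.0  # E[F_FA] = 1 + 2 trace(D)/trace(err)
    d_eigs = trace_d * d_frac
    D = _embed(basis, (q[:, :7] * d_eigs) @ q[:, :7].T)

    g_frac = d_frac[:6] ** 2
    g_frac /= g_frac.sum()
    trace_g = 3.1e-4
    g_eigs = trace_g * g_frac
    # G shares D's leading eigenstructure only partially: each genetic
    # eigenvector is its developmental counterpart rotated by 41.5 degrees
    # toward an orthogonal direction, so the gmax-dmax vector correlation is
    # cos(41.5 deg) = 0.75 by construction
    theta_dg = np.radians(41.5)
    q_g = np.cos(theta_dg) * q[:, :6] + np.sin(theta_dg) * q[:, 6:12]
    G = _embed(basis, (q_g * g_eigs) @ q_g.T)

    q_e = _orthonormal(build_rng, t_dim)
    e_frac = 0.75 ** np.arange(t_dim)
    e_frac /= e_frac.sum()
    trace_e = 1.95e-4
    E = _embed(basis, (q_e * (trace_e * e_frac)) @ q_e.T)

    def unit_tangent(r: np.random.Generator) -> np.ndarray:
        z = r.standard_normal(t_dim)
        return basis @ (z / np.linalg.norm(z))

    da = 0.004 * unit_tangent(build_rng)
    allometry = 0.0365 * unit_tangent(build_rng)
    beta_t = 0.010 * _vector_with_target_eval(build_rng, basis, q, d_frac, 0.087)
    beta_l = 0.00128 * _vector_with_target_eval(build_rng, basis, q, d_frac, 0.076)

    populations = [
        ("IT", 41.9),
        ("FL", 30.5),
        ("SC", 33.9),
        ("NC", 35.8),
        ("MI", 42.6),
    ]
    return SimulationParams(
        n_families=54,
        offspring_per_family=6,
        populations=populations,
        temperatures=[19.0, 27.0],
        k_landmarks=k,
        mean_shape=mean,
        G_true=G,
        E_true=E,
        D_true=D,
        sigma_meas=np.full(2 * k, sigma_meas),
        DA_vector=da,
        allometry_vector=allometry,
        beta_latitude=beta_l,
        beta_temperature=beta_t,
        size_distribution=(np.log(800.0), 0.15),
        n_replicates=2,
        n_extra_individuals=110,
        extra_population="NC",
        seed=seed,
    )


def calibration_design(
    n_families: int = 40,
    offspring_per_family: int = 5,
    seed: int = 0,
) -> SimulationParams:
    """Well-conditioned design for estimator cross-checks.

    All true covariance matrices have full rank within the shape tangent space
    with gently decaying spectra, and genetic/developmental signal is strong
    relative to measurement error, so moment and REML estimators sit in the
    interior of the parameter space on balanced data.
    """
    k = 8
    mean = normalize(_DEFAULT_MEAN_SHAPE)
    basis = tangent_basis(mean)
    t_dim = basis.shape[1]
    build_rng = np.random.default_rng(777)

    def full_rank(trace: float, decay: float, r: np.random.Generator) -> np.ndarray:
        qm = _orthonormal(r, t_dim)
        frac = decay ** np.arange(t_dim)
        frac /= frac.sum()
        return _embed(basis, (qm * (trace * frac)) @ qm.T)

    D = full_rank(2.0e-4, 0.85, build_rng)
    G = full_rank(8.0e-4, 0.85, build_rng)
    E = full_rank(1.0e-4, 0.9, build_rng)
    zero = np.zeros(2 * k)
    return SimulationParams(
        n_families=n_families,
        offspring_per_family=offspring_per_family,
        populations=[("A", 31.0), ("B", 36.0)],
        temperatures=[19.0, 27.0],
        k_landmarks=k,
        mean_shape=mean,
        G_true=G,
        E_true=E,
        D_true=D,
        sigma_meas=np.full(2 * k, 0.002),
        DA_vector=0.003 * basis[:, 0],
        allometry_vector=zero.copy(),
        beta_latitude=zero.copy(),
        beta_temperature=zero.copy(),
        size_distribution=(np.log(800.0), 0.1),
        n_replicates=2,
        n_extra_individuals=0,
        seed=seed,
    )
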