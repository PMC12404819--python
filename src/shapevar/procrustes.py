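"""Generalized Procrustes alignment and bilateral-symmetry Procrustes ANOVA.

Paired structures (left/right legs) are analyzed under matching symmetry: the
designated side is mirrored, then all records — both sides, both replicate
measurements — enter a single simultaneous GPA. The Goodall-style ANOVA
decomposes total Procrustes variance into individual, side (directional
asymmetry), individual x side (fluctuating asymmetry) and measurement-error
components, with residual-randomization permutation tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._geometry import center, centroid_size, normalize, optimal_rotation
from .io import LandmarkConfiguration

__all__ = [
    "reflect",
    "ProcrustesAligner",
    "gpa",
    "AlignedDataset",
    "symmetry_anova",
    "SymmetryAnovaTable",
    "AlignmentError",
]


class AlignmentError(ValueError):
    """Degenerate configuration or failed alignment."""


def reflect(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Mirror a configuration about the y-axis (x -> -x); landmark order kept."""
    return dc_replace(config, coords=config.coords * np.array([-1.0, 1.0]))


@dataclass
class AlignedDataset:
    """Procrustes shape coordinates plus record bookkeeping.

    ``shape_coords`` rows are flattened (k, 2) configurations, each centered at
    the origin with unit centroid size; ``consensus`` is the mean of the
    aligned coordinates.
    """

    shape_coords: np.ndarray  # n_records x p
    centroid_sizes: np.ndarray  # n_records, pre-scaling sizes
    consensus: np.ndarray  # (k, 2)
    keys: pd.DataFrame  # specimen_id, side, replicate
    n_iterations: int
    final_change: float
    reflect_side: str

    @property
    def n_records(self) -> int:
        return self.shape_coords.shape[0]

    @property
    def p(self) -> int:
        return self.shape_coords.shape[1]

    @property
    def k(self) -> int:
        return self.p // 2

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{ax}{j + 1}" for j in range(self.k) for ax in ("x", "y")]
        df = self.keys.copy()
        df[cols] = self.shape_coords
        df["centroid_size"] = self.centroid_sizes
        return df


class ProcrustesAligner:
    """Generalized Procrustes superimposition (partial Procrustes, 2D).

    Iteratively centers, scales to unit centroid size and rotates every
    configuration onto the running consensus (rotation only, no reflection;
    the ``reflect_side`` is mirrored first), until the root-mean-square change
    of the consensus falls below ``tol``.

    Follows the fit/transform convention: ``fit`` aligns the training records
    and stores the consensus; ``transform`` aligns further configurations onto
    the fitted consensus.

    Parameters
    ----------
    reflect_side : {'left', 'right', None}
        Which side to mirror before alignment (matching symmetry).
    tol : float
        Convergence tolerance on the consensus RMS change.
    max_iter : int
        Iteration cap.
    """

    def __init__(self, reflect_side: str | None = "left", tol: float = 1e-10,
                 max_iter: int = 100):
        self.reflect_side = reflect_side
        self.tol = tol
        self.max_iter = max_iter

    # minimal sklearn-compatible parameter plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {"reflect_side": self.reflect_side, "tol": self.tol, "max_iter": self.max_iter}

    def set_params(self, **params) -> "ProcrustesAligner":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def _prepare(self, configs: Sequence[LandmarkConfiguration]) -> tuple[np.ndarray, np.ndarray]:
        mats = []
        sizes = []
        for c in configs:
            coords = c.coords
            if self.reflect_side is not None and c.side == self.reflect_side:
                coords = coords * np.array([-1.0, 1.0])
            cs = centroid_size(coords)
            if cs <= 0 or not np.isfinite(cs):
                raise AlignmentError(
                    f"degenerate configuration (zero centroid size): {c.key}"
                )
            mats.append(center(coords) / cs)
            sizes.append(cs)
        return np.asarray(mats), np.asarray(sizes)

    def fit(self, configs: Sequence[LandmarkConfiguration]) -> "ProcrustesAligner":
        if len(configs) < 2:
            raise AlignmentError("GPA requires at least two configurations")
        ks = {c.k for c in configs}
        if len(ks) > 1:
            raise AlignmentError(f"unequal landmark counts: {sorted(ks)}")
        mats, sizes = self._prepare(configs)
        consensus = mats[0].copy()
        n_iter = 0
        change = np.inf
        for n_iter in range(1, self.max_iter + 1):
            aligned = np.array([m @ optimal_rotation(m, consensus) for m in mats])
            new_consensus = normalize(aligned.mean(axis=0))
            change = float(np.sqrt(((new_consensus - consensus) ** 2).mean()))
            consensus = new_consensus
            if change < self.tol:
                break
        aligned = np.array([m @ optimal_rotation(m, consensus) for m in mats])
        self.consensus_ = aligned.mean(axis=0)
        self.shape_coords_ = aligned.reshape(len(configs), -1)
        self.centroid_sizes_ = sizes
        self.keys_ = pd.DataFrame(
            {
                "specimen_id": [c.specimen_id for c in configs],
                "side": [c.side for c in configs],
                "replicate": [c.replicate for c in configs],
            }
        )
        self.n_iter_ = n_iter
        self.final_change_ = change
        return self

    def transform(self, configs: Sequence[LandmarkConfiguration]) -> np.ndarray:
        if not hasattr(self, "consensus_"):
            raise AlignmentError("aligner is not fitted")
        mats, _ = self._prepare(configs)
        target = normalize(self.consensus_)
        aligned = np.array([m @ optimal_rotation(m, target) for m in mats])
        return aligned.reshape(len(configs), -1)

    def fit_transform(self, configs: Sequence[LandmarkConfiguration]) -> np.ndarray:
        return self.fit(configs).shape_coords_

    @property
    def aligned_(self) -> AlignedDataset:
        return AlignedDataset(
            shape_coords=self.shape_coords_,
            centroid_sizes=self.centroid_sizes_,
            consensus=self.consensus_,
            keys=self.keys_,
            n_iterations=self.n_iter_,
            final_change=self.final_change_,
            reflect_side=self.reflect_side or "",
        )


def gpa(
    configs: Sequence[LandmarkConfiguration],
    reflect_side: str | None = "left",
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedDataset:
    """Align all configurations simultaneously; returns an AlignedDataset."""
    return ProcrustesAligner(reflect_side=reflect_side, tol=tol, max_iter=max_iter).fit(
        configs
    ).aligned_


def align_to_reference(aligned: AlignedDataset, reference: np.ndarray) -> AlignedDataset:
    """Rigidly rotate a whole aligned dataset onto a reference shape.

    GPA fixes orientation only up to a global rotation; comparisons against an
    externally defined frame (e.g. simulation truth) require rotating the
    consensus onto the reference first. Shape relationships within the dataset
    are untouched.
    """
    ref = normalize(np.asarray(reference, dtype=float))
    rot = optimal_rotation(normalize(aligned.consensus), ref)
    n, k = aligned.n_records, aligned.k
    coords = aligned.shape_coords.reshape(n, k, 2) @ rot
    return AlignedDataset(
        shape_coords=coords.reshape(n, -1),
        centroid_sizes=aligned.centroid_sizes,
        consensus=aligned.consensus @ rot,
        keys=aligned.keys,
        n_iterations=aligned.n_iterations,
        final_change=aligned.final_change,
        reflect_side=aligned.reflect_side,
    )


# ---------------------------------------------------------------------------
# bilateral symmetry ANOVA


@dataclass
class SymmetryAnovaTable:
    """Goodall-type decomposition of Procrustes variance.

    Sums of squares are summed over all shape variables (univariate-sum
    Goodall form, not per-landmark MANOVA). The fluctuating-asymmetry term
    (individual x side) is tested against the measurement-error mean square;
    Z is the standardized position of the observed F in the permutation
    distribution.
    """

    table: pd.DataFrame  # index: individual, side, individual_x_side, error, total
    n_individuals: int
    n_sides: int
    n_replicates: int
    n_permutations: int
    seed: int | None

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]

    @property
    def fa_proportion(self) -> float:
        return float(self.table.loc["individual_x_side", "prop_SS"])

    def to_json(self) -> str:
        out = self.table.reset_index().rename(columns={"index": "term"})
        return out.to_json(orient="records", indent=2)


def _cell_stats(y: np.ndarray, idx: np.ndarray, n_groups: int) -> np.ndarray:
    """Group means of rows of y by integer index (n_groups x p)."""
    sums = np.zeros((n_groups, y.shape[1]))
    np.add.at(sums, idx, y)
    counts = np.bincount(idx, minlength=n_groups)
    return sums / counts[:, None]


def _interaction_f(
    y: np.ndarray,
    ind_idx: np.ndarray,
    side_idx: np.ndarray,
    cell_idx: np.ndarray,
    n_ind: int,
    n_side: int,
    r: int,
) -> tuple[float, float, float]:
    """(SS_interaction, SS_error, F) for a balanced two-way layout."""
    grand = y.mean(axis=0)
    ind_means = _cell_stats(y, ind_idx, n_ind)
    side_means = _cell_stats(y, side_idx, n_side)
    cell_means = _cell_stats(y, cell_idx, n_ind * n_side)
    # cell (i, s) has flat index i * n_side + s
    i_of_cell = np.arange(n_ind * n_side) // n_side
    s_of_cell = np.arange(n_ind * n_side) % n_side
    inter = cell_means - ind_means[i_of_cell] - side_means[s_of_cell] + grand
    ss_int = r * float((inter**2).sum())
    ss_err = float(((y - cell_means[cell_idx]) ** 2).sum())
    df_int = (n_ind - 1) * (n_side - 1)
    df_err = n_ind * n_side * (r - 1)
    f = (ss_int / df_int) / (ss_err / df_err)
    return ss_int, ss_err, f


def symmetry_anova(
    aligned: AlignedDataset,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> SymmetryAnovaTable:
    """Procrustes ANOVA for matching bilateral symmetry.

    Requires a (near-)balanced design: individuals missing any (side,
    replicate) cell are dropped with a warning. With a single replicate the
    measurement-error term is undefined and an error is raised.

    The permutation test for the fluctuating-asymmetry term randomizes the
    residuals of the reduced model (individual + side), i.e. an RRPP-style
    residual randomization; the p-value is the upper tail of the permuted F
    distribution and Z standardizes the observed F by the permutation mean
    and SD.
    """
    keys = aligned.keys
    y_all = aligned.shape_coords
    sides = sorted(keys["side"].unique())
    reps = sorted(keys["replicate"].unique())
    if len(reps) < 2:
        raise ValueError("measurement-error term undefined with a single replicate")
    counts = keys.groupby("specimen_id").size()
    complete = counts[counts == len(sides) * len(reps)].index
    if len(complete) < len(counts):
        warnings.warn(
            f"dropping {len(counts) - len(complete)} individuals with incomplete "
            "side/replicate cells",
            stacklevel=2,
        )
    if len(complete) < 2:
        raise ValueError("symmetry ANOVA requires at least 2 complete individuals")
    mask = keys["specimen_id"].isin(complete).to_numpy()
    keys = keys.loc[mask].reset_index(drop=True)
    y = y_all[mask]

    individuals = np.sort(keys["specimen_id"].unique())
    n = len(individuals)
    s = len(sides)
    r = len(reps)
    ind_idx = pd.Categorical(keys["specimen_id"], categories=individuals).codes.astype(int)
    side_idx = pd.Categorical(keys["side"], categories=sides).codes.astype(int)
    cell_idx = ind_idx * s + side_idx

    grand = y.mean(axis=0)
    ind_means = _cell_stats(y, ind_idx, n)
    side_means = _cell_stats(y, side_idx, s)
    ss_ind = s * r * float(((ind_means - grand) ** 2).sum())
    ss_side = n * r * float(((side_means - grand) ** 2).sum())
    ss_int, ss_err, f_int = _interaction_f(y, ind_idx, side_idx, cell_idx, n, s, r)
    ss_total = float(((y - grand) ** 2).sum())

    df = {
        "individual": n - 1,
        "side": s - 1,
        "individual_x_side": (n - 1) * (s - 1),
        "error": n * s * (r - 1),
    }
    ss = {
        "individual": ss_ind,
        "side": ss_side,
        "individual_x_side": ss_int,
        "error": ss_err,
    }
    ms = {k: ss[k] / df[k] for k in ss}
    # individual and side are tested over the interaction MS; FA over error MS
    f_stats = {
        "individual": ms["individual"] / ms["individual_x_side"],
        "side": ms["side"] / ms["individual_x_side"],
        "individual_x_side": f_int,
        "error": np.nan,
    }

    z_val = p_val = None
    if n_permutations and n_permutations > 0:
        rng = np.random.default_rng(seed)
        fitted = ind_means[ind_idx] + side_means[side_idx] - grand
        resid = y - fitted
        f_perm = np.empty(n_permutations)
        for b in range(n_permutations):
            y_star = fitted + resid[rng.permutation(len(resid))]
            _, _, f_perm[b] = _interaction_f(
                y_star, ind_idx, side_idx, cell_idx, n, s, r
            )
        p_val = float((1 + (f_perm >= f_int).sum()) / (1 + n_permutations))
        sd = f_perm.std(ddof=1)
        z_val = float((f_int - f_perm.mean()) / sd) if sd > 0 else np.inf

    rows = []
    for term in ("individual", "side", "individual_x_side", "error"):
        rows.append(
            {
                "term": term,
                "SS": ss[term],
                "df": df[term],
                "MS": ms[term],
                "prop_SS": ss[term] / ss_total,
                "F": f_stats[term],
                "Z": z_val if term == "individual_x_side" else np.nan,
                "p": p_val if term == "individual_x_side" else np.nan,
            }
        )
    rows.append(
        {
            "term": "total",
            "SS": ss_total,
            "df": n * s * r - 1,
            "MS": np.nan,
            "prop_SS": 1.0,
            "F": np.nan,
            "Z": np.nan,
            "p": np.nan,
        }
    )
    table = pd.DataFrame(rows).set_index("term")
    return SymmetryAnovaTable(
        table=table,
        n_individuals=n,
        n_sides=s,
        n_replicates=r,
        n_permutations=n_permutations or 0,
        seed=seed,
    )
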