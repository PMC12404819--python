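"""Reading, writing and validating bilateral landmark data.

Two interchange formats are supported: the TPS format produced by the tps
digitizing tools (LM=/ID=/IMAGE=/SCALE= keys) and a richer tabular CSV with
one row per digitization and explicit metadata columns. TPS carries no
metadata slots, so specimen identity, side and replicate are encoded in the
ID field as ``<specimen>_<L|R>_<rep>``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SIDES = ("left", "right")

_SIDE_CODE = {"L": "left", "R": "right"}
_CODE_SIDE = {"left": "L", "right": "R"}

METADATA_COLUMNS = ("family_id", "population_id", "latitude", "temperature", "species", "cohort")


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Structurally valid input that violates dataset invariants."""


class SchemaError(ValueError):
    """Missing or misnamed mandatory columns."""


@dataclass
class LandmarkConfiguration:
    """One digitization of one side of one individual."""

    specimen_id: str
    side: str
    replicate: int
    coords: np.ndarray  # (k, 2), digitizing units
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError(
                f"coords must be (k, 2); got {self.coords.shape} for {self.specimen_id}"
            )
        if np.isnan(self.coords).any():
            raise ValidationError(f"NaN coordinate in configuration {self.key}")
        if self.side not in SIDES:
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if int(self.replicate) < 1:
            raise ValidationError("replicate must be a positive integer")
        self.replicate = int(self.replicate)

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.specimen_id, self.side, self.replicate)


@dataclass
class DesignTable:
    """Per-specimen metadata: family, population, latitude, temperature.

    Each specimen appears exactly once; each family maps to exactly one
    population and latitude.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if "specimen_id" not in t.columns:
            raise SchemaError("design table requires a specimen_id column")
        if t["specimen_id"].duplicated().any():
            dupes = t.loc[t["specimen_id"].duplicated(), "specimen_id"].tolist()
            raise ValidationError(f"duplicate specimen_id in design table: {dupes[:5]}")
        if {"family_id", "population_id"} <= set(t.columns):
            fam = t.dropna(subset=["family_id"])
            per_family = fam.groupby("family_id")["population_id"].nunique()
            if (per_family > 1).any():
                bad = per_family[per_family > 1].index.tolist()
                raise ValidationError(f"family mapped to multiple populations: {bad[:5]}")
        if {"family_id", "latitude"} <= set(t.columns):
            fam = t.dropna(subset=["family_id"])
            per_family = fam.groupby("family_id")["latitude"].nunique()
            if (per_family > 1).any():
                bad = per_family[per_family > 1].index.tolist()
                raise ValidationError(f"family mapped to multiple latitudes: {bad[:5]}")
        self.table = t.reset_index(drop=True)

    def lookup(self, specimen_id: str) -> pd.Series:
        rows = self.table[self.table["specimen_id"] == specimen_id]
        if rows.empty:
            raise KeyError(specimen_id)
        return rows.iloc[0]

    @property
    def specimen_ids(self) -> list[str]:
        return self.table["specimen_id"].tolist()


@dataclass
class ValidationReport:
    n_configurations: int
    n_individuals: int
    n_sides: int
    n_replicates: int
    k_landmarks: int | None
    imbalance_flags: list[str]
    specimens_missing_metadata: list[str]

    @property
    def balanced(self) -> bool:
        return not self.imbalance_flags

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_configurations": self.n_configurations,
                "n_individuals": self.n_individuals,
                "n_sides": self.n_sides,
                "n_replicates": self.n_replicates,
                "k_landmarks": self.k_landmarks,
                "balanced": self.balanced,
                "imbalance_flags": self.imbalance_flags,
                "specimens_missing_metadata": self.specimens_missing_metadata,
            },
            indent=2,
        )


def _check_unique_keys(configs: Sequence[LandmarkConfiguration]) -> None:
    seen: set[tuple[str, str, int]] = set()
    for c in configs:
        if c.key in seen:
            raise ValidationError(f"duplicate (specimen, side, replicate): {c.key}")
        seen.add(c.key)


def _check_equal_k(configs: Sequence[LandmarkConfiguration]) -> None:
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise ValidationError(f"inconsistent landmark counts across configurations: {sorted(ks)}")


_ID_RE = re.compile(r"^(?P<specimen>.+)_(?P<side>[LR])_(?P<rep>\d+)$")


def _parse_tps_id(raw: str, record_index: int) -> tuple[str, str, int]:
    m = _ID_RE.match(raw.strip())
    if not m:
        raise ParseError(
            f"record {record_index}: ID {raw!r} does not follow '<specimen>_<L|R>_<rep>'"
        )
    return m.group("specimen"), _SIDE_CODE[m.group("side")], int(m.group("rep"))


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS landmark file into configurations.

    Supports the LM=, ID=, IMAGE= and SCALE= keys; SCALE is applied
    multiplicatively to the coordinates; CURVES/POINTS blocks are ignored.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record_index = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise ParseError(f"record {record_index}: expected LM=, got {line!r}")
        try:
            n_lm = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise ParseError(f"record {record_index}: bad LM count in {line!r}") from exc
        i += 1
        coords = []
        while len(coords) < n_lm and i < len(lines):
            parts = lines[i].split()
            if len(parts) != 2:
                raise ParseError(
                    f"record {record_index}: LM={n_lm} declared but only "
                    f"{len(coords)} coordinate lines found before {lines[i]!r}"
                )
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ParseError(
                    f"record {record_index}: non-numeric coordinate line {lines[i]!r}"
                ) from exc
            i += 1
        if len(coords) < n_lm:
            raise ParseError(
                f"record {record_index}: LM={n_lm} declared but only {len(coords)} "
                "coordinate lines present"
            )
        rec_id = None
        image = None
        scale = None
        in_curve = False
        while i < len(lines):
            line = lines[i].strip()
            upper = line.upper()
            if upper.startswith("LM="):
                break
            if upper.startswith("CURVES=") or upper.startswith("POINTS="):
                in_curve = True
            elif upper.startswith("ID="):
                rec_id = line.split("=", 1)[1]
                in_curve = False
            elif upper.startswith("IMAGE="):
                image = line.split("=", 1)[1]
            elif upper.startswith("SCALE="):
                scale = float(line.split("=", 1)[1])
            elif line and not in_curve and "=" not in line:
                raise ParseError(f"record {record_index}: unexpected line {line!r}")
            i += 1
        if rec_id is None:
            raise ParseError(f"record {record_index}: missing ID= line")
        specimen, side, rep = _parse_tps_id(rec_id, record_index)
        arr = np.asarray(coords, dtype=float)
        if scale is not None:
            arr = arr * scale
        metadata = {}
        if image:
            metadata["image"] = image
        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen, side=side, replicate=rep, coords=arr, metadata=metadata
            )
        )
        record_index += 1
    _check_equal_k(configs)
    _check_unique_keys(configs)
    return configs


def write_tps(configs: Iterable[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations to a TPS file (LM/coordinates/IMAGE/ID records)."""
    out_lines: list[str] = []
    for c in configs:
        out_lines.append(f"LM={c.k}")
        for x, y in c.coords:
            out_lines.append(f"{x:.6f} {y:.6f}")
        if c.metadata.get("image"):
            out_lines.append(f"IMAGE={c.metadata['image']}")
        out_lines.append(f"ID={c.specimen_id}_{_CODE_SIDE[c.side]}_{c.replicate}")
    Path(path).write_text("\n".join(out_lines) + "\n")


def read_table(path: str | Path) -> tuple[list[LandmarkConfiguration], DesignTable]:
    """Read the canonical CSV format.

    Mandatory columns: specimen_id, side, replicate, x1..xk, y1..yk.
    Recognized metadata columns (family_id, population_id, latitude,
    temperature, species, cohort) are joined into the DesignTable.
    """
    df = pd.read_csv(path)
    mandatory = {"specimen_id", "side", "replicate"}
    missing = mandatory - set(df.columns)
    if missing:
        raise SchemaError(f"missing mandatory column(s): {sorted(missing)}")
    x_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"x\d+", c)), key=lambda c: int(c[1:])
    )
    y_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"y\d+", c)), key=lambda c: int(c[1:])
    )
    if not x_cols or [int(c[1:]) for c in x_cols] != [int(c[1:]) for c in y_cols]:
        raise SchemaError("coordinate columns must be paired x1..xk, y1..yk")
    coord_cols = [c for pair in zip(x_cols, y_cols) for c in pair]
    bad = df.index[df[coord_cols].isna().any(axis=1)].tolist()
    if bad:
        raise ValidationError(f"NaN coordinates in rows {bad}")
    configs = []
    for _, row in df.iterrows():
        coords = np.column_stack(
            [row[x_cols].to_numpy(dtype=float), row[y_cols].to_numpy(dtype=float)]
        )
        meta = {
            k: row[k]
            for k in METADATA_COLUMNS
            if k in df.columns and pd.notna(row[k])
        }
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(row["specimen_id"]),
                side=str(row["side"]),
                replicate=int(row["replicate"]),
                coords=coords,
                metadata=meta,
            )
        )
    _check_equal_k(configs)
    _check_unique_keys(configs)
    meta_cols = [c for c in METADATA_COLUMNS if c in df.columns]
    design_df = (
        df[["specimen_id"] + meta_cols]
        .astype({"specimen_id": str})
        .drop_duplicates(subset="specimen_id")
        .reset_index(drop=True)
    )
    return configs, DesignTable(design_df)


def write_table(
    configs: Sequence[LandmarkConfiguration],
    path: str | Path,
    design: DesignTable | None = None,
) -> None:
    """Write configurations (plus optional design metadata) as CSV."""
    if not configs:
        raise ValueError("no configurations to write")
    k = configs[0].k
    rows = []
    for c in configs:
        row: dict = {"specimen_id": c.specimen_id, "side": c.side, "replicate": c.replicate}
        for j in range(k):
            row[f"x{j + 1}"] = c.coords[j, 0]
            row[f"y{j + 1}"] = c.coords[j, 1]
        rows.append(row)
    df = pd.DataFrame(rows)
    if design is not None:
        meta_cols = [c for c in design.table.columns if c != "specimen_id"]
        df = df.merge(design.table[["specimen_id"] + meta_cols], on="specimen_id", how="left")
    df.to_csv(path, index=False)


def validate_design(
    configs: Sequence[LandmarkConfiguration], design: DesignTable | None = None
) -> ValidationReport:
    """Report design completeness: individuals x sides x replicates.

    Never raises; imbalance (missing side or replicate cells) is reported as
    flags so callers can decide how to proceed.
    """
    if not configs:
        return ValidationReport(0, 0, 0, 0, None, [], [])
    specimens = sorted({c.specimen_id for c in configs})
    sides = sorted({c.side for c in configs})
    reps = sorted({c.replicate for c in configs})
    flags: list[str] = []
    have = {(c.specimen_id, c.side, c.replicate) for c in configs}
    for s in specimens:
        for side in sides:
            for r in reps:
                if (s, side, r) not in have:
                    flags.append(f"{s}: missing side={side} replicate={r}")
    missing_meta: list[str] = []
    if design is not None:
        known = set(design.specimen_ids)
        missing_meta = [s for s in specimens if s not in known]
    return ValidationReport(
        n_configurations=len(configs),
        n_individuals=len(specimens),
        n_sides=len(sides),
        n_replicates=len(reps),
        k_landmarks=configs[0].k,
        imbalance_flags=flags,
        specimens_missing_metadata=missing_meta,
    )
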