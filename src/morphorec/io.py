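"""Landmark dataset containers and I/O.

Configurations are k landmarks in 3D with per-landmark roles
(``fixed`` anatomical points or ``surface_semilandmark``) plus specimen
metadata (population, sex, side).  Two file formats are supported:

* TPS with ``LM3=<k>`` blocks (3D dialect; ``SCALE=`` applied
  multiplicatively, ``IMAGE=`` ignored),
* a wide CSV with columns ``specimen_id, population, sex, side,
  lm1_x, lm1_y, lm1_z, ...`` (metadata columns may instead live in a JSON
  sidecar keyed by specimen id).

Landmark indices are 1-based at every user-facing interface, matching the
anatomical numbering convention of the zygomatic scheme (landmarks 1-7
fixed, 8-30 surface semilandmarks).  Internally coordinates are stored as
``(k, 3)`` float arrays and flattened row-major, so flat index
``3*(i-1) + axis`` addresses landmark i.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DatasetError, ParseError, SchemaError

FIXED = "fixed"
SEMILANDMARK = "surface_semilandmark"

#: Anatomical names of the seven fixed zygomatic landmarks (1-7).
ZYGOMATIC_FIXED_NAMES = (
    "inferior zygotemporale",
    "superior zygotemporale",
    "frontomalare temporale",
    "frontomalare orbitale",
    "zygomaxillare orbitale",
    "inferior zygomaxillare",
    "inferior zygosphenoid",
)


def default_roles(k: int) -> tuple[str, ...]:
    """Per-landmark roles: the zygomatic scheme (7 fixed + 23 semilandmarks)
    when k == 30, otherwise all landmarks are treated as fixed."""
    if k == 30:
        return (FIXED,) * 7 + (SEMILANDMARK,) * 23
    return (FIXED,) * k


def default_labels(k: int, roles: Sequence[str] | None = None) -> tuple[str, ...]:
    roles = tuple(roles) if roles is not None else default_roles(k)
    labels = []
    for i, role in enumerate(roles, start=1):
        if k == 30 and role == FIXED and i <= 7:
            labels.append(ZYGOMATIC_FIXED_NAMES[i - 1])
        elif role == SEMILANDMARK:
            labels.append(f"semi-{i}")
        else:
            labels.append(f"lm-{i}")
    return tuple(labels)


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen: k landmarks in 3D plus metadata.

    Coordinates must be finite; missing landmarks are never represented
    here (see :class:`morphorec.imputation.DamagedConfiguration`).
    """

    specimen_id: str
    coords: np.ndarray
    roles: tuple[str, ...] = ()
    population: str = "unknown"
    sex: str = "unknown"
    side: str = "unknown"

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise DatasetError(
                f"specimen {self.specimen_id!r}: coords must be (k, 3), "
                f"got {coords.shape}"
            )
        if not np.isfinite(coords).all():
            raise DatasetError(
                f"specimen {self.specimen_id!r}: non-finite coordinates"
            )
        object.__setattr__(self, "coords", coords)
        roles = tuple(self.roles) if self.roles else default_roles(coords.shape[0])
        if len(roles) != coords.shape[0]:
            raise DatasetError(
                f"specimen {self.specimen_id!r}: {len(roles)} roles for "
                f"{coords.shape[0]} landmarks"
            )
        bad = set(roles) - {FIXED, SEMILANDMARK}
        if bad:
            raise DatasetError(f"unknown landmark roles: {sorted(bad)}")
        object.__setattr__(self, "roles", roles)

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray) -> "LandmarkConfiguration":
        return replace(self, coords=np.asarray(coords, dtype=float))


@dataclass(frozen=True)
class LandmarkDataset:
    """An ordered collection of configurations sharing k, roles, labels."""

    configurations: tuple[LandmarkConfiguration, ...]
    landmark_labels: tuple[str, ...] = ()

    def __post_init__(self):
        configs = tuple(self.configurations)
        if not configs:
            raise DatasetError("empty dataset: no landmark configurations")
        k = configs[0].k
        roles = configs[0].roles
        for c in configs:
            if c.k != k:
                raise DatasetError(
                    f"mixed landmark counts: specimen {c.specimen_id!r} has "
                    f"k={c.k}, expected {k}"
                )
            if c.roles != roles:
                raise DatasetError(
                    f"specimen {c.specimen_id!r} has different landmark roles"
                )
        ids = [c.specimen_id for c in configs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate specimen ids: {dupes}")
        object.__setattr__(self, "configurations", configs)
        labels = tuple(self.landmark_labels) or default_labels(k, roles)
        if len(labels) != k:
            raise DatasetError(f"{len(labels)} labels for {k} landmarks")
        object.__setattr__(self, "landmark_labels", labels)

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    def __getitem__(self, i: int) -> LandmarkConfiguration:
        return self.configurations[i]

    @property
    def k(self) -> int:
        return self.configurations[0].k

    @property
    def roles(self) -> tuple[str, ...]:
        return self.configurations[0].roles

    @property
    def specimen_ids(self) -> tuple[str, ...]:
        return tuple(c.specimen_id for c in self.configurations)

    def coords_array(self) -> np.ndarray:
        """Stack all configurations into an (n, k, 3) array."""
        return np.stack([c.coords for c in self.configurations])

    def get(self, specimen_id: str) -> LandmarkConfiguration:
        for c in self.configurations:
            if c.specimen_id == specimen_id:
                return c
        raise KeyError(specimen_id)

    def drop(self, specimen_id: str) -> "LandmarkDataset":
        kept = tuple(
            c for c in self.configurations if c.specimen_id != specimen_id
        )
        if len(kept) == len(self.configurations):
            raise KeyError(specimen_id)
        return LandmarkDataset(kept, self.landmark_labels)

    def filter_population(self, population: str) -> "LandmarkDataset":
        kept = tuple(
            c for c in self.configurations if c.population == population
        )
        if not kept:
            raise DatasetError(f"no specimens with population {population!r}")
        return LandmarkDataset(kept, self.landmark_labels)


# ---------------------------------------------------------------------------
# TPS format

_TPS_KEY = re.compile(r"^\s*([A-Za-z0-9_]+)\s*=\s*(.*?)\s*$")


def read_tps(
    path: str | Path,
    roles: Sequence[str] | None = None,
) -> LandmarkDataset:
    """Read a 3D TPS file (``LM3=`` blocks).

    ``SCALE=`` lines multiply the record's coordinates; ``IMAGE=`` lines are
    ignored.  Records lacking ``ID=`` are numbered by position.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i, n_record = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _TPS_KEY.match(line)
        if not m or m.group(1).upper() != "LM3":
            raise ParseError(
                f"{path.name}: expected LM3=<count> at line {i + 1}, got "
                f"{line!r}"
            )
        try:
            k = int(m.group(2))
        except ValueError as exc:
            raise ParseError(
                f"{path.name}: bad landmark count {m.group(2)!r} at line "
                f"{i + 1}"
            ) from exc
        i += 1
        pts = []
        while len(pts) < k and i < len(lines):
            row = lines[i].strip()
            if _TPS_KEY.match(row):
                break
            vals = row.split()
            if len(vals) != 3:
                raise ParseError(
                    f"{path.name}: record {n_record + 1}: expected 3 "
                    f"coordinates at line {i + 1}, got {row!r}"
                )
            try:
                pts.append([float(v) for v in vals])
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}: record {n_record + 1}: non-numeric "
                    f"coordinate at line {i + 1}"
                ) from exc
            i += 1
        if len(pts) != k:
            raise ParseError(
                f"{path.name}: record {n_record + 1}: LM3={k} but only "
                f"{len(pts)} coordinate lines present"
            )
        spec_id = None
        scale = None
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            m = _TPS_KEY.match(row)
            if not m:
                raise ParseError(
                    f"{path.name}: record {n_record + 1}: LM3={k} but extra "
                    f"coordinate line at line {i + 1}"
                )
            key = m.group(1).upper()
            if key == "LM3":
                break
            if key == "ID":
                spec_id = m.group(2)
            elif key == "SCALE":
                try:
                    scale = float(m.group(2))
                except ValueError as exc:
                    raise ParseError(
                        f"{path.name}: record {n_record + 1}: bad SCALE "
                        f"{m.group(2)!r}"
                    ) from exc
            # IMAGE= and other keys ignored
            i += 1
        coords = np.asarray(pts, dtype=float)
        if scale is not None:
            coords = coords * scale
        n_record += 1
        configs.append(
            LandmarkConfiguration(
                specimen_id=spec_id if spec_id is not None else str(n_record),
                coords=coords,
                roles=tuple(roles) if roles is not None else (),
            )
        )
    if not configs:
        raise DatasetError(f"{path.name}: empty TPS file, no records found")
    return LandmarkDataset(tuple(configs))


def write_tps(dataset: LandmarkDataset, path: str | Path) -> None:
    """Write a dataset as 3D TPS records (full float precision)."""
    out = []
    for c in dataset:
        out.append(f"LM3={c.k}")
        for x, y, z in c.coords:
            out.append(f"{x:.17g} {y:.17g} {z:.17g}")
        out.append(f"ID={c.specimen_id}")
        out.append("")
    Path(path).write_text("\n".join(out))


# ---------------------------------------------------------------------------
# Wide CSV format

_META_COLS = ("specimen_id", "population", "sex", "side")


def _coord_columns(k: int) -> list[str]:
    return [f"lm{i}_{ax}" for i in range(1, k + 1) for ax in "xyz"]


def read_csv_wide(
    path: str | Path,
    roles: Sequence[str] | None = None,
    metadata: str | Path | Mapping[str, Mapping[str, str]] | None = None,
) -> LandmarkDataset:
    """Read a wide-format landmark CSV.

    Coordinate columns are ``lm<i>_x/_y/_z`` for i = 1..k (k inferred from
    the header).  Metadata columns (population/sex/side) are optional in the
    CSV and may instead come from a JSON sidecar mapping specimen id to a
    metadata dict.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"specimen_id": str})
    if "specimen_id" not in df.columns:
        raise SchemaError(f"{path.name}: missing required column specimen_id")
    lm_cols = [c for c in df.columns if re.fullmatch(r"lm\d+_[xyz]", c)]
    if not lm_cols:
        raise SchemaError(f"{path.name}: no landmark columns lm<i>_x/y/z found")
    k = max(int(re.match(r"lm(\d+)_", c).group(1)) for c in lm_cols)
    expected = _coord_columns(k)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing coordinate columns: {', '.join(missing)}"
        )
    sidecar: Mapping[str, Mapping[str, str]] = {}
    if metadata is not None:
        if isinstance(metadata, (str, Path)):
            sidecar = json.loads(Path(metadata).read_text())
        else:
            sidecar = metadata
    configs = []
    for row_i, row in df.iterrows():
        vals = row[expected]
        bad = vals[pd.to_numeric(vals, errors="coerce").isna()]
        if len(bad):
            raise ParseError(
                f"{path.name}: non-numeric cell in row {row_i + 2}, column "
                f"{bad.index[0]}: {bad.iloc[0]!r}"
            )
        coords = pd.to_numeric(vals).to_numpy(dtype=float).reshape(k, 3)
        meta = dict(sidecar.get(str(row["specimen_id"]), {}))
        for col in ("population", "sex", "side"):
            if col in df.columns and not pd.isna(row[col]):
                meta.setdefault(col, str(row[col]))
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(row["specimen_id"]),
                coords=coords,
                roles=tuple(roles) if roles is not None else (),
                population=meta.get("population", "unknown"),
                sex=meta.get("sex", "unknown"),
                side=meta.get("side", "unknown"),
            )
        )
    return LandmarkDataset(tuple(configs))


def write_csv_wide(dataset: LandmarkDataset, path: str | Path) -> None:
    rows = []
    for c in dataset:
        row: dict[str, object] = {
            "specimen_id": c.specimen_id,
            "population": c.population,
            "sex": c.sex,
            "side": c.side,
        }
        row.update(zip(_coord_columns(c.k), c.coords.reshape(-1)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Antimere reflection

_AXES = {"x": 0, "y": 1, "z": 2}
_FLIP_SIDE = {"left": "right", "right": "left", "unknown": "unknown"}


def reflect_configuration(
    c: LandmarkConfiguration, plane_normal_axis: str = "x"
) -> LandmarkConfiguration:
    """Mirror a configuration across the plane normal to the given axis.

    Used to reflect antimeres (e.g. right zygomatics into left form) before
    pooling sides.  The side flag flips; landmark order is unchanged (the
    zygomatic scheme is side-symmetric, no relabelling is needed).
    """
    try:
        ax = _AXES[plane_normal_axis.lower()]
    except KeyError:
        raise ValueError(
            f"plane_normal_axis must be one of x/y/z, got {plane_normal_axis!r}"
        ) from None
    coords = c.coords.copy()
    coords[:, ax] = -coords[:, ax]
    return replace(c, coords=coords, side=_FLIP_SIDE.get(c.side, "unknown"))
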