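"""Canonical data model for 3D-FISH spot/nucleus records and table I/O.

All stored coordinates are physical micrometres (μm); normalized,
dimensionless quantities are computed downstream and never stored as
inputs.  Voxel indices are 0-based and map to physical space with the
voxel-*center* convention: physical = (index + 0.5) * voxel_size.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CHANNELS = ("classI", "classII", "classIII")

#: Columns of the canonical one-row-per-spot table.
SPOT_TABLE_COLUMNS = [
    "nucleus_id",
    "condition",
    "species",
    "allele_truth",
    "channel",
    "x_um",
    "y_um",
    "z_um",
    "spot_radius_um",
    "nucleus_cx",
    "nucleus_cy",
    "nucleus_cz",
    "nucleus_radius_um",
]


class SchemaError(ValueError):
    """A table is missing required columns or violates the record schema."""


@dataclass(frozen=True)
class Spot:
    """One FISH signal: its MHC-class channel, centroid and radius (μm)."""

    channel: str
    position: np.ndarray  # (3,) μm
    radius: float

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("spot position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not (self.radius > 0):
            raise ValueError("spot radius must be > 0")


@dataclass(frozen=True)
class NucleusGeometry:
    """Nucleus envelope: center (μm) and equivalent-sphere radius (μm).

    `semiaxes`, when given, enables the ellipsoid envelope option: the
    local radius along a ray is then the distance from the center to the
    axis-aligned ellipsoid surface along that ray.
    """

    center: np.ndarray  # (3,) μm
    radius: float
    semiaxes: tuple[float, float, float] | None = None

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("nucleus center must be a finite 3-vector")
        object.__setattr__(self, "center", c)
        if not (self.radius > 0):
            raise ValueError("nucleus radius must be > 0")
        if self.semiaxes is not None and any(s <= 0 for s in self.semiaxes):
            raise ValueError("ellipsoid semiaxes must be > 0")

    def local_radius(self, direction: np.ndarray) -> float:
        """Envelope distance from the center along `direction`.

        Equals `radius` for the default spherical envelope.
        """
        if self.semiaxes is None:
            return self.radius
        d = np.asarray(direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            return min(self.semiaxes)
        u = d / n
        a = np.asarray(self.semiaxes, dtype=float)
        return float(1.0 / np.sqrt(np.sum((u / a) ** 2)))


@dataclass
class CellRecord:
    """One scored nucleus: geometry, labels, and its (expected 6) spots."""

    nucleus_id: str
    species: str
    condition: str
    geometry: NucleusGeometry
    spots: list[Spot] = field(default_factory=list)
    allele_truth: list[int] | None = None  # per-spot ground-truth allele index

    def spots_by_channel(self) -> dict[str, list[Spot]]:
        out: dict[str, list[Spot]] = {ch: [] for ch in CHANNELS}
        for s in self.spots:
            out[s.channel].append(s)
        return out

    def validate(self, tolerance: float = 1e-6) -> None:
        """Check channel multiplicity and spot containment.

        `tolerance` is an absolute μm slack on the envelope test.
        """
        by_ch = self.spots_by_channel()
        for ch, spots in by_ch.items():
            if len(spots) > 2:
                raise SchemaError(
                    f"nucleus {self.nucleus_id}: {len(spots)} spots in channel {ch} (max 2)"
                )
        for s in self.spots:
            v = s.position - self.geometry.center
            if np.linalg.norm(v) > self.geometry.local_radius(v) + tolerance:
                raise SchemaError(
                    f"nucleus {self.nucleus_id}: spot {s.channel} at {s.position} "
                    "lies outside the nucleus envelope"
                )


def voxel_to_physical(index: Sequence[float], voxel_size: Sequence[float]) -> np.ndarray:
    """Map a 0-based voxel index to the physical position of the voxel center (μm).

    physical = (index + 0.5) * voxel_size, per axis.  Fractional indices
    (e.g. intensity-weighted centroids) are accepted.
    """
    idx = np.asarray(index, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    if np.any(vs <= 0):
        raise ValueError("voxel_size components must be > 0")
    if np.any(idx < 0):
        raise ValueError("voxel indices must be non-negative")
    return (idx + 0.5) * vs


def physical_to_voxel(position: Sequence[float], voxel_size: Sequence[float]) -> np.ndarray:
    """Inverse of :func:`voxel_to_physical` (returns fractional indices)."""
    vs = np.asarray(voxel_size, dtype=float)
    if np.any(vs <= 0):
        raise ValueError("voxel_size components must be > 0")
    return np.asarray(position, dtype=float) / vs - 0.5


def _sniff_delimiter(path: Path) -> str:
    sample = Path(path).read_text().splitlines()
    if not sample:
        return "\t"
    try:
        return csv.Sniffer().sniff(sample[0], delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def write_spot_table(records: Iterable[CellRecord], path: str | Path, sep: str = "\t") -> None:
    """Write cell records as a one-row-per-spot TSV/CSV table."""
    rows = []
    for rec in records:
        truth = rec.allele_truth if rec.allele_truth is not None else [-1] * len(rec.spots)
        for spot, al in zip(rec.spots, truth):
            rows.append(
                {
                    "nucleus_id": rec.nucleus_id,
                    "condition": rec.condition,
                    "species": rec.species,
                    "allele_truth": al,
                    "channel": spot.channel,
                    "x_um": spot.position[0],
                    "y_um": spot.position[1],
                    "z_um": spot.position[2],
                    "spot_radius_um": spot.radius,
                    "nucleus_cx": rec.geometry.center[0],
                    "nucleus_cy": rec.geometry.center[1],
                    "nucleus_cz": rec.geometry.center[2],
                    "nucleus_radius_um": rec.geometry.radius,
                }
            )
    pd.DataFrame(rows, columns=SPOT_TABLE_COLUMNS).to_csv(path, sep=sep, index=False)


def read_spot_table(path: str | Path, dialect: str | None = None) -> list[CellRecord]:
    """Read a one-row-per-spot table into validated :class:`CellRecord` s.

    Parameters
    ----------
    path:
        TSV or CSV file with the columns of ``SPOT_TABLE_COLUMNS``
        (``allele_truth`` is optional).
    dialect:
        Delimiter override; by default sniffed from the header line.

    Raises
    ------
    SchemaError
        If a required column is missing, a coordinate is missing/non-finite
        (the message carries the offending row numbers), or a nucleus has
        more than two spots in one channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = dialect or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep)
    required = [c for c in SPOT_TABLE_COLUMNS if c != "allele_truth"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    coord_cols = ["x_um", "y_um", "z_um", "spot_radius_um", "nucleus_radius_um"]
    bad = df.index[df[coord_cols].isna().any(axis=1)]
    if len(bad):
        # +2: 1-based data rows after the header line
        raise SchemaError(f"{path}: rows with missing coordinates: {[int(i) + 2 for i in bad]}")

    records: list[CellRecord] = []
    for nid, grp in df.groupby("nucleus_id", sort=False):
        first = grp.iloc[0]
        geom = NucleusGeometry(
            center=np.array([first.nucleus_cx, first.nucleus_cy, first.nucleus_cz]),
            radius=float(first.nucleus_radius_um),
        )
        spots = [
            Spot(channel=r.channel, position=np.array([r.x_um, r.y_um, r.z_um]),
                 radius=float(r.spot_radius_um))
            for r in grp.itertuples()
        ]
        truth = None
        if "allele_truth" in grp.columns and (grp["allele_truth"] >= 0).all():
            truth = [int(a) for a in grp["allele_truth"]]
        rec = CellRecord(
            nucleus_id=str(nid),
            species=str(first.species),
            condition=str(first.condition),
            geometry=geom,
            spots=spots,
            allele_truth=truth,
        )
        rec.validate(tolerance=1e-3)
        records.append(rec)
    return records
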