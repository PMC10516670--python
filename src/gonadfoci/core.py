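"""Domain types shared by every pipeline stage.

The package works on multi-channel 3D fluorescence volumes of C. elegans
germlines.  All arrays are indexed ``(channel, z, y, x)``; physical voxel
spacing is given in nanometres as ``(z, y, x)``.  Voxel ``i`` is centred at
``(i + 0.5) * spacing`` (voxel-centre convention), so distances between
adjacent voxel centres equal the spacing along that axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Column order of the detection-table TSV interchange format.
DETECTION_COLUMNS = [
    "focus_id",
    "species",
    "z_vox",
    "y_vox",
    "x_vox",
    "z_nm",
    "y_nm",
    "x_nm",
    "peak_height",
    "nucleus_id",
    "rel_position_pct",
]


@dataclass(frozen=True)
class ChannelMeta:
    """A fluorescence channel: label plus emission wavelength in nm.

    The emission wavelength feeds the diffraction-limit colocalization
    threshold (0.61 lambda / NA).
    """

    name: str
    emission_nm: float

    def __post_init__(self) -> None:
        if not self.emission_nm > 0:
            raise ValueError(f"emission_nm must be > 0, got {self.emission_nm}")


@dataclass
class ImageStack:
    """A multi-channel 3D intensity volume with physical calibration.

    Parameters
    ----------
    voxels : ndarray, shape (C, Z, Y, X)
        Non-negative finite intensities, any numeric dtype.
    spacing : tuple of float
        Physical voxel size in nm for (z, y, x); all entries positive.
    channels : list of ChannelMeta
        One entry per channel, in array order.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channels: list[ChannelMeta]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be 4D (C,Z,Y,X), got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values (z,y,x) nm, got {self.spacing}")
        if len(self.channels) != self.voxels.shape[0]:
            raise ValueError(
                f"channel count {len(self.channels)} does not match "
                f"first array dimension {self.voxels.shape[0]}"
            )
        if not np.issubdtype(self.voxels.dtype, np.number):
            raise ValueError(f"non-numeric voxel dtype {self.voxels.dtype}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensities must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel_index(self, name: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.name == name:
                return i
        raise KeyError(f"unknown channel {name!r}; have {[c.name for c in self.channels]}")

    def channel(self, name: str) -> np.ndarray:
        """The (Z, Y, X) volume of one channel."""
        return self.voxels[self.channel_index(name)]

    def vox_to_nm(self, position_vox: Sequence[float]) -> tuple[float, float, float]:
        """Physical (z, y, x) nm of a voxel index, voxel-centre convention."""
        return tuple((float(p) + 0.5) * s for p, s in zip(position_vox, self.spacing))

    def nm_to_vox(self, position_nm: Sequence[float]) -> tuple[float, float, float]:
        return tuple(float(p) / s - 0.5 for p, s in zip(position_nm, self.spacing))


@dataclass
class Focus:
    """A called immunofluorescence focus: a 3D intensity maximum."""

    id: str
    species: str
    position_vox: tuple[int, int, int]
    position_nm: tuple[float, float, float]
    peak_height: float
    nucleus_id: Optional[str] = None
    rel_position_pct: Optional[float] = None


def polygon_centroid(polygon: np.ndarray) -> tuple[float, float]:
    """Area centroid of a simple 2D polygon (shoelace formula).

    Falls back to the vertex mean for degenerate (zero-area) polygons.
    """
    p = np.asarray(polygon, dtype=float)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area2 = cross.sum()
    if abs(area2) < 1e-12:
        return float(x.mean()), float(y.mean())
    cx = ((x + xn) * cross).sum() / (3.0 * area2)
    cy = ((y + yn) * cross).sum() / (3.0 * area2)
    return float(cx), float(cy)


@dataclass
class NucleusROI:
    """A nucleus outline: simple 2D polygon in voxel xy coordinates."""

    id: str
    polygon: np.ndarray  # (N, 2) array of (x, y) vertices
    row_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or self.polygon.shape[0] < 3:
            raise ValueError(f"ROI {self.id}: polygon needs >= 3 (x,y) vertices")

    @property
    def centroid_xy(self) -> tuple[float, float]:
        return polygon_centroid(self.polygon)


@dataclass
class DetectionTable:
    """Foci as a tidy table plus provenance.

    Wraps a pandas DataFrame with the columns in :data:`DETECTION_COLUMNS`.
    ``overlap_candidates`` holds, for multiply-assigned foci, the list of
    candidate ROI ids awaiting resolution.
    """

    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    overlap_candidates: dict = field(default_factory=dict)  # focus_id -> [roi ids]

    def __post_init__(self) -> None:
        missing = [c for c in DETECTION_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"detection table missing columns {missing}")
        ids = self.df["focus_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate focus id {dup!r}")
        df = self.df[DETECTION_COLUMNS].reset_index(drop=True).copy()
        # Normalize dtypes so write/read round trips compare field-for-field.
        if len(df):
            df["focus_id"] = df["focus_id"].astype(str)
            df["species"] = df["species"].astype(str)
            for c in ("z_vox", "y_vox", "x_vox"):
                df[c] = df[c].astype(np.int64)
            for c in ("z_nm", "y_nm", "x_nm", "peak_height", "rel_position_pct"):
                df[c] = pd.to_numeric(df[c]).astype(np.float64)
            nid = df["nucleus_id"]
            df["nucleus_id"] = [None if pd.isna(v) else str(v) for v in nid]
            df["nucleus_id"] = df["nucleus_id"].astype(object)
        else:
            df = df.astype(
                {
                    "focus_id": str,
                    "species": str,
                    "z_vox": np.int64,
                    "y_vox": np.int64,
                    "x_vox": np.int64,
                    "z_nm": np.float64,
                    "y_nm": np.float64,
                    "x_nm": np.float64,
                    "peak_height": np.float64,
                    "nucleus_id": object,
                    "rel_position_pct": np.float64,
                }
            )
        self.df = df

    @classmethod
    def from_foci(cls, foci: Sequence[Focus], provenance: Optional[dict] = None) -> "DetectionTable":
        rows = []
        for f in foci:
            rows.append(
                {
                    "focus_id": f.id,
                    "species": f.species,
                    "z_vox": f.position_vox[0],
                    "y_vox": f.position_vox[1],
                    "x_vox": f.position_vox[2],
                    "z_nm": f.position_nm[0],
                    "y_nm": f.position_nm[1],
                    "x_nm": f.position_nm[2],
                    "peak_height": f.peak_height,
                    "nucleus_id": f.nucleus_id,
                    "rel_position_pct": f.rel_position_pct,
                }
            )
        df = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
        return cls(df=df, provenance=dict(provenance or {}))

    def to_foci(self) -> list[Focus]:
        out = []
        for _, r in self.df.iterrows():
            nid = r["nucleus_id"]
            rel = r["rel_position_pct"]
            out.append(
                Focus(
                    id=str(r["focus_id"]),
                    species=str(r["species"]),
                    position_vox=(int(r["z_vox"]), int(r["y_vox"]), int(r["x_vox"])),
                    position_nm=(float(r["z_nm"]), float(r["y_nm"]), float(r["x_nm"])),
                    peak_height=float(r["peak_height"]),
                    nucleus_id=None if pd.isna(nid) else str(nid),
                    rel_position_pct=None if pd.isna(rel) else float(rel),
                )
            )
        return out

    def validate_against_rois(self, rois: Sequence[NucleusROI]) -> None:
        known = {r.id for r in rois}
        assigned = self.df["nucleus_id"].dropna()
        unknown = set(assigned) - known
        if unknown:
            raise ValueError(f"nucleus ids not among known ROIs: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DetectionTable):
            return NotImplemented
        return self.df.equals(other.df)
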