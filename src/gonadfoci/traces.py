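"""Traced-chromosome analytics: lengths, crossover positions, fusion calls.

Chromosomes traced through SIM image stacks arrive as 3D polylines in μm
with attached crossover (CO) site points.  Length is the polyline arc
length; a CO site's position is reported as arc distance to the nearer
chromosome end divided by total length, so values lie in [0, 0.5] with 0 a
terminal CO and 0.5 a central one.  Chromosomes longer than 15 μm are
classified as mnT12 fusion chromosomes (strict >); all unfused chromosomes
fall below that cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

FUSION_CUTOFF_UM = 15.0
DEFAULT_SNAP_TOLERANCE_UM = 0.5


@dataclass
class ChromosomeTrace:
    """An ordered 3D polyline (μm) with attached CO-site points."""

    id: str
    points_um: np.ndarray  # (N, 3) xyz
    co_sites_um: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self) -> None:
        self.points_um = np.asarray(self.points_um, dtype=float).reshape(-1, 3)
        self.co_sites_um = np.asarray(self.co_sites_um, dtype=float).reshape(-1, 3)
        if len(self.points_um) < 2:
            raise ValueError(f"trace {self.id}: a polyline needs >= 2 points")
        seg = np.diff(self.points_um, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) == 0):
            raise ValueError(f"trace {self.id}: consecutive points must be distinct")

    @property
    def is_fusion(self) -> bool:
        return classify_fusion(self)


def trace_length(trace: ChromosomeTrace) -> float:
    """Arc length in μm: sum of consecutive-point Euclidean distances."""
    seg = np.diff(trace.points_um, axis=0)
    return float(np.linalg.norm(seg, axis=1).sum())


def classify_fusion(trace: ChromosomeTrace, cutoff_um: float = FUSION_CUTOFF_UM) -> bool:
    """Fusion (mnT12) iff traced length strictly exceeds the cutoff (15 μm)."""
    return trace_length(trace) > cutoff_um


def _project_arc_length(trace: ChromosomeTrace, point: np.ndarray) -> tuple[float, float]:
    """Arc-length coordinate of the polyline point nearest ``point``.

    Returns (arc_length_at_projection, distance_to_polyline), scanning every
    segment and interpolating within the best one.
    """
    p = np.asarray(point, dtype=float)
    pts = trace.points_um
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best = (np.inf, 0.0)
    for i in range(len(seg)):
        t = np.dot(p - pts[i], seg[i]) / (seg_len[i] ** 2)
        t = min(max(t, 0.0), 1.0)
        proj = pts[i] + t * seg[i]
        d = float(np.linalg.norm(p - proj))
        if d < best[0]:
            best = (d, cum[i] + t * seg_len[i])
    return best[1], best[0]


def co_relative_position(
    trace: ChromosomeTrace,
    co_point: Sequence[float],
    snap_tolerance_um: float = DEFAULT_SNAP_TOLERANCE_UM,
) -> float:
    """Relative CO position: arc distance to the nearer end / total length.

    The CO point is snapped to the nearest point on the polyline; a point
    farther than ``snap_tolerance_um`` from the trace is an error.  The
    result is <= 0.5 by construction and invariant under reversal of the
    polyline's point order.
    """
    total = trace_length(trace)
    arc, dist = _project_arc_length(trace, np.asarray(co_point))
    if dist > snap_tolerance_um:
        raise ValueError(
            f"CO point {tuple(np.asarray(co_point))} is {dist:.3f} μm from trace "
            f"{trace.id}, beyond the {snap_tolerance_um} μm snap tolerance"
        )
    return min(arc, total - arc) / total


def co_distribution_histogram(
    traces: Sequence[ChromosomeTrace],
    bins: int = 10,
    cutoff_um: float = FUSION_CUTOFF_UM,
    snap_tolerance_um: float = DEFAULT_SNAP_TOLERANCE_UM,
) -> pd.DataFrame:
    """Binned distribution of relative CO positions, split by fusion class.

    Histogram over [0, 0.5]; within each class (fusion / non-fusion) the
    bin fractions sum to 1.  Raises when no trace carries a CO site.
    """
    positions: dict[str, list[float]] = {"fusion": [], "non-fusion": []}
    for tr in traces:
        cls = "fusion" if classify_fusion(tr, cutoff_um) else "non-fusion"
        for co in tr.co_sites_um:
            positions[cls].append(co_relative_position(tr, co, snap_tolerance_um))
    if not any(positions.values()):
        raise ValueError("no CO sites on any trace")
    edges = np.linspace(0.0, 0.5, bins + 1)
    rows = []
    for cls, vals in positions.items():
        if not vals:
            continue
        hist, _ = np.histogram(vals, bins=edges)
        frac = hist / hist.sum()
        for i in range(bins):
            rows.append(
                {
                    "class": cls,
                    "bin_low": edges[i],
                    "bin_high": edges[i + 1],
                    "count": int(hist[i]),
                    "fraction": float(frac[i]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trace file I/O: canonical JSON dialect and SWC polylines

def read_traces(path: Union[str, Path]) -> list[ChromosomeTrace]:
    """Read traces from the JSON dialect or an SWC file (one path per chromosome)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".swc":
        return _read_swc(path)
    data = json.loads(path.read_text())
    out = []
    for rec in data["traces"]:
        out.append(
            ChromosomeTrace(
                id=str(rec["id"]),
                points_um=np.asarray(rec["points_um"], float),
                co_sites_um=np.asarray(rec.get("co_sites_um", []), float).reshape(-1, 3),
            )
        )
    return out


def write_traces(traces: Sequence[ChromosomeTrace], path: Union[str, Path]) -> None:
    payload = {
        "traces": [
            {
                "id": t.id,
                "points_um": t.points_um.tolist(),
                "co_sites_um": t.co_sites_um.tolist(),
            }
            for t in traces
        ]
    }
    Path(path).write_text(json.dumps(payload))


def _read_swc(path: Path) -> list[ChromosomeTrace]:
    """SWC: columns id type x y z radius parent; parent -1 starts a new path."""
    paths: list[list[list[float]]] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        x, y, z, parent = float(parts[2]), float(parts[3]), float(parts[4]), int(parts[6])
        if parent == -1:
            paths.append([])
        if not paths:
            raise ValueError(f"malformed SWC {path}: node before any root")
        paths[-1].append([x, y, z])
    return [
        ChromosomeTrace(id=f"{path.stem}_{i}", points_um=np.asarray(p))
        for i, p in enumerate(paths)
    ]
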