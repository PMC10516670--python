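"""Assignment of detected foci to nucleus ROIs and gonad-position bookkeeping.

A focus belongs to a nucleus iff its (x, y) — taken from its 3D maximum,
which max projection preserves — lies inside the nucleus polygon, boundary
included.  Foci falling in overlapping ROIs are flagged and resolved to the
nearest ROI centroid with an auditable report (the original counts resolved
such overlaps by eye).  Relative gonad position is the nucleus centroid's x
expressed as a percentage of the quantified region, 0% at the distal end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .core import DetectionTable, Focus, NucleusROI


def _roi_shapes(rois: Sequence[NucleusROI]) -> dict[str, Polygon]:
    shapes = {}
    for r in rois:
        poly = Polygon(np.asarray(r.polygon))
        if not poly.is_valid or poly.area == 0:
            raise ValueError(f"degenerate polygon for ROI {r.id}")
        shapes[r.id] = poly
    return shapes


def point_in_roi(x: float, y: float, roi: NucleusROI) -> bool:
    """Boundary-inclusive point-in-polygon test."""
    return Polygon(np.asarray(roi.polygon)).covers(Point(x, y))


def assign_foci(foci: Sequence[Focus], rois: Sequence[NucleusROI]) -> DetectionTable:
    """Assign each focus to the ROI containing its xy position.

    Foci contained in no ROI keep a null ``nucleus_id``; foci contained in
    more than one ROI are recorded in ``overlap_candidates`` for
    :func:`resolve_overlaps`, with ``nucleus_id`` provisionally set to the
    first candidate in ROI-id order.
    """
    shapes = _roi_shapes(rois)
    table = DetectionTable.from_foci(foci)
    assigned: list[Optional[str]] = []
    overlaps: dict[str, list[str]] = {}
    for f in foci:
        _, y, x = f.position_vox
        hits = sorted(rid for rid, poly in shapes.items() if poly.covers(Point(x, y)))
        if not hits:
            assigned.append(None)
        else:
            assigned.append(hits[0])
            if len(hits) > 1:
                overlaps[f.id] = hits
    table.df["nucleus_id"] = pd.Series(assigned, dtype=object)
    table.overlap_candidates = overlaps
    return table


@dataclass
class OverlapResolution:
    focus_id: str
    candidates: list[str]
    chosen: str
    centroid_distances: dict[str, float]


def resolve_overlaps(
    table: DetectionTable, rois: Sequence[NucleusROI]
) -> tuple[DetectionTable, list[OverlapResolution]]:
    """Reassign multiply-assigned foci to the nearest-centroid candidate ROI.

    Ties go to the lexicographically smaller ROI id.  Returns the resolved
    table and a report listing every resolution for human review.  A table
    without overlap flags is returned unchanged.
    """
    if not table.overlap_candidates:
        return table, []
    centroids = {r.id: r.centroid_xy for r in rois}
    report = []
    df = table.df.copy()
    for fid, cands in sorted(table.overlap_candidates.items()):
        row = df.loc[df["focus_id"] == fid].iloc[0]
        x, y = float(row["x_vox"]), float(row["y_vox"])
        dists = {
            rid: float(np.hypot(x - centroids[rid][0], y - centroids[rid][1])) for rid in cands
        }
        chosen = min(sorted(cands), key=lambda rid: dists[rid])
        df.loc[df["focus_id"] == fid, "nucleus_id"] = chosen
        report.append(
            OverlapResolution(
                focus_id=fid, candidates=list(cands), chosen=chosen, centroid_distances=dists
            )
        )
    out = DetectionTable(df=df, provenance=dict(table.provenance))
    return out, report


def relative_positions(
    table: DetectionTable,
    rois: Sequence[NucleusROI],
    region_x_start: float,
    region_x_end: float,
) -> DetectionTable:
    """Attach each focus's relative gonad position (0-100%) via its nucleus.

    ``rel_position_pct = 100 * (centroid_x - start) / (end - start)`` using
    the ROI centroid's x.  Centroids outside the region are clamped with a
    warning.  Unassigned foci keep a null position.
    """
    if not region_x_end > region_x_start:
        raise ValueError("region_x_end must exceed region_x_start")
    span = region_x_end - region_x_start
    pct = {}
    for r in rois:
        cx = r.centroid_xy[0]
        p = 100.0 * (cx - region_x_start) / span
        if p < 0 or p > 100:
            warnings.warn(
                f"ROI {r.id} centroid x={cx:.1f} outside region "
                f"[{region_x_start}, {region_x_end}]; clamped"
            )
            p = min(max(p, 0.0), 100.0)
        pct[r.id] = p
    df = table.df.copy()
    df["rel_position_pct"] = [
        pct.get(nid, np.nan) if nid is not None else np.nan for nid in df["nucleus_id"]
    ]
    out = DetectionTable(df=df, provenance=dict(table.provenance))
    out.overlap_candidates = dict(table.overlap_candidates)
    return out


def count_foci_per_nucleus(table: DetectionTable) -> tuple[pd.DataFrame, int]:
    """Per-nucleus focus counts by species, plus the unassigned-focus count.

    Returns a DataFrame with columns (nucleus_id, species, n_foci).  The sum
    of counts plus the unassigned count equals the table length
    (conservation).
    """
    df = table.df
    assigned = df[df["nucleus_id"].notna()]
    unassigned = len(df) - len(assigned)
    counts = (
        assigned.groupby(["nucleus_id", "species"], sort=True)
        .size()
        .rename("n_foci")
        .reset_index()
    )
    return counts, unassigned
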