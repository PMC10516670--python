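"""Chromosome-axis association scoring.

An axis mask is thresholded from the axis-protein channel (HTP-3), dilated
by one voxel along z to capture foci adjacent or tethered to the axis, and
each focus is scored associated iff the mask is true at its maximum's voxel.
The association fraction is (axis-associated foci) / (total foci); genotype
comparisons use the Fisher exact test on the associated / not-associated
counts.

The upstream mask recipe used for the original figures is external to this
package; a thresholding step (fixed value or Otsu) stands in for it, with
full provenance recorded so an exact recipe can be slotted in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .core import Focus, ImageStack
from .coloc import proportion_ci


@dataclass
class AxisMask:
    """Boolean (Z, Y, X) volume marking axis signal, with provenance."""

    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("axis mask must be 3D (Z, Y, X)")


def build_axis_mask(
    stack: ImageStack,
    axis_channel: str,
    method: str = "otsu",
    value: Optional[float] = None,
) -> AxisMask:
    """Threshold the axis channel into a binary mask.

    ``method`` is ``"fixed"`` (requires ``value``) or ``"otsu"``; the mask
    is intensity >= threshold.
    """
    vol = stack.channel(axis_channel)
    if method == "fixed":
        if value is None:
            raise ValueError("fixed-threshold masking requires a value")
        thr = float(value)
    elif method == "otsu":
        thr = float(threshold_otsu(np.asarray(vol)))
    else:
        raise ValueError(f"unknown mask method {method!r} (use 'fixed' or 'otsu')")
    return AxisMask(
        mask=vol >= thr,
        provenance={"channel": axis_channel, "method": method, "threshold": thr, "dilated_z": 0},
    )


def dilate_z(mask: AxisMask, voxels: int = 1) -> AxisMask:
    """Dilate the mask along z only: out[z,y,x] = any in[z',y,x], |z-z'| <= voxels."""
    if voxels < 0:
        raise ValueError("dilation must be >= 0 voxels")
    m = mask.mask
    out = m.copy()
    for d in range(1, voxels + 1):
        out[d:] |= m[:-d]
        out[:-d] |= m[d:]
    prov = dict(mask.provenance)
    prov["dilated_z"] = prov.get("dilated_z", 0) + voxels
    return AxisMask(mask=out, provenance=prov)


@dataclass
class AxisAssociationResult:
    associated: int
    total: int
    fraction: float
    ci95: tuple[float, float]


def axis_association_fraction(foci: Sequence[Focus], mask: AxisMask) -> AxisAssociationResult:
    """Fraction of foci whose maximum voxel falls inside the (dilated) mask.

    Returns counts, fraction and a Wilson 95% CI.  Raises if any focus lies
    outside the mask volume.
    """
    m = mask.mask
    assoc = 0
    for f in foci:
        z, y, x = f.position_vox
        if not (0 <= z < m.shape[0] and 0 <= y < m.shape[1] and 0 <= x < m.shape[2]):
            raise ValueError(f"focus {f.id} at {f.position_vox} lies outside mask volume {m.shape}")
        if m[z, y, x]:
            assoc += 1
    total = len(foci)
    frac = assoc / total if total else float("nan")
    ci = proportion_ci(assoc, total) if total else (float("nan"), float("nan"))
    return AxisAssociationResult(associated=assoc, total=total, fraction=frac, ci95=ci)
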