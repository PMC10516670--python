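"""3D maxima-based focus detection.

Re-implements the ImageJ 3D Maxima Finder parameterization used for all
focus counts: a voxel is called as a focus iff

1. its intensity is at least ``min_peak_height``;
2. it is a (strict-or-plateau) local maximum within an anisotropic
   ellipsoidal neighborhood with semi-axes ``(radius_z, radius_xy,
   radius_xy)`` voxels;
3. its prominence over the local background — intensity minus the minimum
   on the shell surrounding the neighborhood — is at least ``noise``;
4. among surviving candidates that lie within one neighborhood of each
   other, only the brightest is kept (ties broken toward the smallest
   (z, y, x)), which also collapses plateau maxima to a single call.

The shell in (3) is the set of voxels inside the ellipsoid scaled by 2 but
outside the core neighborhood; out-of-bounds shell voxels are ignored.
Defaults follow the plugin: radius_xy = radius_z = 1.5 voxels, noise = 100
intensity units.  ``min_peak_height`` has no universal default; it is
calibrated per image from background fluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import Focus, ImageStack, NucleusROI

DEFAULT_RADIUS_XY = 1.5
DEFAULT_RADIUS_Z = 1.5
DEFAULT_NOISE = 100.0


@dataclass(frozen=True)
class DetectionParams:
    """Spot-calling parameters, in the 3D Maxima Finder convention.

    Radii are in voxels (not nm); fractional radii define the ellipsoid
    inclusion test (dz/rz)^2 + (dy/rxy)^2 + (dx/rxy)^2 <= 1.
    """

    min_peak_height: float
    radius_xy: float = DEFAULT_RADIUS_XY
    radius_z: float = DEFAULT_RADIUS_Z
    noise: float = DEFAULT_NOISE

    def __post_init__(self) -> None:
        if self.radius_xy <= 0 or self.radius_z <= 0:
            raise ValueError("radii must be > 0")
        if self.min_peak_height < 0 or self.noise < 0:
            raise ValueError("min_peak_height and noise must be >= 0")


def ellipsoid_offsets(radius_z: float, radius_xy: float, scale: float = 1.0) -> np.ndarray:
    """Integer (dz,dy,dx) offsets with (dz/rz)^2+(dy/rxy)^2+(dx/rxy)^2 <= scale^2, excluding origin."""
    rz, rxy = radius_z * scale, radius_xy * scale
    nz, nxy = int(np.floor(rz)), int(np.floor(rxy))
    out = []
    for dz in range(-nz, nz + 1):
        for dy in range(-nxy, nxy + 1):
            for dx in range(-nxy, nxy + 1):
                if dz == dy == dx == 0:
                    continue
                if (dz / rz) ** 2 + (dy / rxy) ** 2 + (dx / rxy) ** 2 <= 1.0 + 1e-12:
                    out.append((dz, dy, dx))
    return np.asarray(out, dtype=int).reshape(-1, 3)


def _shell_offsets(radius_z: float, radius_xy: float) -> np.ndarray:
    """Offsets in the 2x-scaled ellipsoid but outside the core neighborhood."""
    core = {tuple(o) for o in ellipsoid_offsets(radius_z, radius_xy)}
    outer = ellipsoid_offsets(radius_z, radius_xy, scale=2.0)
    return np.asarray([o for o in outer if tuple(o) not in core], dtype=int).reshape(-1, 3)


def _offsets_to_footprint(offsets: np.ndarray, include_center: bool) -> np.ndarray:
    r = np.abs(offsets).max(axis=0) if len(offsets) else np.zeros(3, int)
    fp = np.zeros(2 * r + 1, dtype=bool)
    for o in offsets:
        fp[tuple(o + r)] = True
    if include_center:
        fp[tuple(r)] = True
    return fp


def find_maxima_3d(
    stack: ImageStack,
    channel: str,
    params: DetectionParams,
    mask: Optional[np.ndarray] = None,
    id_prefix: Optional[str] = None,
) -> list[Focus]:
    """Detect foci in one channel as filtered 3D local maxima.

    Parameters
    ----------
    stack : ImageStack
    channel : channel label to detect in
    params : DetectionParams
    mask : optional boolean array, either (Y, X) — applied to every z plane —
        or the full (Z, Y, X) shape.  Signal outside the mask is cleared
        before detection, mirroring the ROI-cleared volumes the counts were
        derived from; no focus is ever reported outside the mask.

    Returns
    -------
    list of Focus, ordered by (z, y, x) of the maximum.
    """
    vol = np.asarray(stack.channel(channel), dtype=float)
    zyx = vol.shape
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape == zyx[1:]:
            mask = np.broadcast_to(mask[None], zyx)
        elif mask.shape != zyx:
            raise ValueError(f"mask shape {mask.shape} matches neither {zyx[1:]} nor {zyx}")
        vol = np.where(mask, vol, 0.0)

    core = ellipsoid_offsets(params.radius_z, params.radius_xy)
    shell = _shell_offsets(params.radius_z, params.radius_xy)

    fp_core = _offsets_to_footprint(core, include_center=True)
    max_f = ndimage.maximum_filter(vol, footprint=fp_core, mode="constant", cval=-np.inf)
    cand = (vol >= max_f) & (vol >= params.min_peak_height)

    if len(shell):
        fp_shell = _offsets_to_footprint(shell, include_center=False)
        shell_min = ndimage.minimum_filter(vol, footprint=fp_shell, mode="constant", cval=np.inf)
        cand &= (vol - shell_min) >= params.noise

    if mask is not None:
        cand &= mask

    coords = np.argwhere(cand)
    if len(coords) == 0:
        return []
    heights = vol[tuple(coords.T)]
    # Brightest-first greedy suppression; ties toward smallest (z, y, x).
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], -heights))
    coords, heights = coords[order], heights[order]
    rz, rxy = params.radius_z, params.radius_xy
    accepted: list[int] = []
    for i in range(len(coords)):
        z, y, x = coords[i]
        ok = True
        for j in accepted:
            dz, dy, dx = coords[i] - coords[j]
            if (dz / rz) ** 2 + (dy / rxy) ** 2 + (dx / rxy) ** 2 <= 1.0 + 1e-12:
                ok = False
                break
        if ok:
            accepted.append(i)

    kept = sorted(accepted, key=lambda i: tuple(coords[i]))
    prefix = id_prefix if id_prefix is not None else channel
    foci = []
    for k, i in enumerate(kept):
        pos = tuple(int(v) for v in coords[i])
        foci.append(
            Focus(
                id=f"{prefix}_{k:05d}",
                species=channel,
                position_vox=pos,
                position_nm=stack.vox_to_nm(pos),
                peak_height=float(heights[i]),
            )
        )
    return foci


def calibrate_min_peak_height(
    stack: ImageStack, channel: str, background_rois: Sequence[NucleusROI]
) -> float:
    """Starting 'Minimum Peak Height': the max intensity over background ROIs.

    The ROIs must sample pure background (no true foci); the returned value
    is the starting point of the iterative threshold search, which the
    caller refines.  If an ROI covers a real spot the returned value is at
    least that spot's peak and detection will under-call — this is a
    documented misuse, not an error.
    """
    if not background_rois:
        raise ValueError("at least one background ROI is required")
    from skimage.draw import polygon2mask

    vol = stack.channel(channel)
    _, ny, nx = vol.shape
    best = -np.inf
    for roi in background_rois:
        # polygon2mask expects (row, col) = (y, x) vertex order
        m = polygon2mask((ny, nx), np.asarray(roi.polygon)[:, ::-1])
        if m.any():
            best = max(best, float(vol[:, m].max()))
    if not np.isfinite(best):
        raise ValueError("background ROIs cover no voxels")
    return best
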