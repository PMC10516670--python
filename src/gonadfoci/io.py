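"""Readers and writers for image stacks, ROI polygons and detection tables.

Images are plain or OME TIFF z-stacks; ROIs come either from the package's
canonical JSON dialect ``{"rois": [{"id": ..., "xy": [[x, y], ...]}]}`` or
from ImageJ ``.roi`` / ``.zip`` polygon archives; detection tables are
UTF-8, tab-delimited TSV with a fixed column set.
"""

from __future__ import annotations

import json
import struct
import zipfile
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .core import DETECTION_COLUMNS, ChannelMeta, DetectionTable, ImageStack, NucleusROI

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# image stacks

def read_stack(
    path: PathLike,
    spacing: Optional[Sequence[float]] = None,
    channels: Optional[Sequence[ChannelMeta]] = None,
) -> ImageStack:
    """Read a multi-channel z-stack TIFF into an ImageStack.

    The on-disk plane layout is normalized to (channel, z, y, x).  A 3D
    series is interpreted as ``(C*Z, Y, X)`` pages and reshaped using the
    declared channel count.  OME voxel-size metadata, when present, is used
    only if the caller passes no ``spacing``.

    Parameters
    ----------
    path : path to a TIFF / OME-TIFF file
    spacing : (z, y, x) voxel size in nm; overrides file metadata
    channels : channel metadata; required when the file does not carry
        channel labels

    Raises
    ------
    FileNotFoundError, ValueError
        Missing file; plane count incompatible with the declared channels;
        non-numeric data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        file_spacing = _ome_spacing_nm(tf)
    if arr.dtype.kind not in "uif":
        raise ValueError(f"non-numeric TIFF data dtype {arr.dtype}")
    if channels is None:
        raise ValueError("channel metadata must be supplied")
    n_ch = len(channels)

    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        pages = arr.shape[0]
        if pages % n_ch != 0:
            raise ValueError(
                f"channel/plane mismatch: {pages} planes are not divisible by "
                f"{n_ch} declared channels"
            )
        # Writers here use CZYX order flattened as (C*Z) pages.
        arr = arr.reshape(n_ch, pages // n_ch, *arr.shape[1:])
    elif arr.ndim == 4:
        if arr.shape[0] != n_ch:
            if arr.shape[1] == n_ch:  # ZCYX layout
                arr = np.moveaxis(arr, 1, 0)
            else:
                raise ValueError(
                    f"channel/plane mismatch: axis sizes {arr.shape[:2]} do not "
                    f"match {n_ch} declared channels"
                )
    else:
        raise ValueError(f"unsupported TIFF dimensionality {arr.ndim}")

    if spacing is None:
        spacing = file_spacing
    if spacing is None:
        raise ValueError("no voxel spacing supplied and none found in file metadata")
    return ImageStack(voxels=arr, spacing=tuple(spacing), channels=list(channels))


def write_stack(stack: ImageStack, path: PathLike) -> None:
    """Write an ImageStack as an OME-TIFF with voxel-size metadata (nm -> um)."""
    sz, sy, sx = stack.spacing
    tifffile.imwrite(
        str(path),
        stack.voxels,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": sz / 1000.0,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": sy / 1000.0,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": sx / 1000.0,
            "PhysicalSizeXUnit": "µm",
        },
        ome=True,
    )


def _ome_spacing_nm(tf: "tifffile.TiffFile") -> Optional[tuple[float, float, float]]:
    try:
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                unit_scale = {"nm": 1.0, "µm": 1000.0, "um": 1000.0, "mm": 1e6}
                vals = []
                for ax in ("Z", "Y", "X"):
                    v = px.get(f"PhysicalSize{ax}")
                    if v is None:
                        return None
                    u = px.get(f"PhysicalSize{ax}Unit", "µm")
                    vals.append(float(v) * unit_scale.get(u, 1000.0))
                return tuple(vals)
    except Exception:
        return None
    return None


def max_project(stack: ImageStack, channel: str) -> np.ndarray:
    """Maximum-intensity projection of one channel along z: out[y,x] = max_z in[z,y,x]."""
    return stack.channel(channel).max(axis=0)


# ---------------------------------------------------------------------------
# ROIs

def read_rois(path: PathLike) -> list[NucleusROI]:
    """Read nucleus ROI polygons from JSON, ImageJ .roi, or ImageJ .zip.

    Ids are stable across re-reads: taken from the JSON record, the archive
    entry name, or the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        rois = _read_rois_json(path)
    elif suffix == ".roi":
        rois = [_parse_imagej_roi(path.read_bytes(), path.stem)]
    elif suffix == ".zip":
        rois = []
        with zipfile.ZipFile(path) as zf:
            for name in sorted(zf.namelist()):
                if name.lower().endswith(".roi"):
                    rois.append(_parse_imagej_roi(zf.read(name), Path(name).stem))
    else:
        raise ValueError(f"unsupported ROI file type {suffix!r}")
    if not rois:
        raise ValueError(f"empty ROI archive {path}")
    return rois


def write_rois(rois: Sequence[NucleusROI], path: PathLike) -> None:
    """Write ROIs in the canonical JSON dialect."""
    payload = {"rois": [{"id": r.id, "xy": np.asarray(r.polygon, float).tolist()} for r in rois]}
    Path(path).write_text(json.dumps(payload, indent=1))


def _read_rois_json(path: Path) -> list[NucleusROI]:
    data = json.loads(path.read_text())
    out = []
    for rec in data["rois"]:
        out.append(NucleusROI(id=str(rec["id"]), polygon=np.asarray(rec["xy"], float)))
    return out


# ImageJ ROI type codes (from the ImageJ source): polygon=0, freehand=7.
_IJ_POLYGON_TYPES = {0, 7}


def _parse_imagej_roi(buf: bytes, default_id: str) -> NucleusROI:
    """Decode an ImageJ binary .roi record (polygon and freehand types only)."""
    if len(buf) < 64 or buf[:4] != b"Iout":
        raise ValueError("not an ImageJ ROI file (bad magic)")
    roi_type = buf[6]
    if roi_type not in _IJ_POLYGON_TYPES:
        raise ValueError(f"unsupported ROI type code {roi_type} (polygon ROIs only)")
    top, left, _bottom, _right, n = struct.unpack(">5h", buf[8:18])
    if n < 3:
        raise ValueError("polygon ROI needs >= 3 vertices")
    xs = struct.unpack(f">{n}h", buf[64 : 64 + 2 * n])
    ys = struct.unpack(f">{n}h", buf[64 + 2 * n : 64 + 4 * n])
    poly = np.column_stack([np.asarray(xs) + left, np.asarray(ys) + top]).astype(float)
    return NucleusROI(id=default_id, polygon=poly)


def write_imagej_roi(roi: NucleusROI, path: PathLike) -> None:
    """Write a polygon ROI in ImageJ's binary .roi format (for interchange tests)."""
    poly = np.asarray(roi.polygon)
    xs = np.round(poly[:, 0]).astype(int)
    ys = np.round(poly[:, 1]).astype(int)
    left, top = int(xs.min()), int(ys.min())
    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 228)  # version
    header[6] = 0  # polygon
    struct.pack_into(">5h", header, 8, top, left, int(ys.max()), int(xs.max()), len(xs))
    body = struct.pack(f">{len(xs)}h", *(xs - left)) + struct.pack(f">{len(ys)}h", *(ys - top))
    Path(path).write_bytes(bytes(header) + body)


# ---------------------------------------------------------------------------
# detection tables

def write_detection_table(table: DetectionTable, path: PathLike) -> None:
    """Write a detection table as UTF-8 TSV ('.' decimal, one header row).

    Floats are serialized with repr-level precision so the round trip is
    lossless.
    """
    table.df.to_csv(path, sep="\t", index=False, encoding="utf-8", float_format="%.17g")


def read_detection_table(path: PathLike) -> DetectionTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", encoding="utf-8")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed TSV {path}: {exc}") from exc
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed detection table {path}: missing columns {missing}")
    return DetectionTable(df=df)
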