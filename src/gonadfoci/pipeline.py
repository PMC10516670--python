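"""End-to-end orchestration: one config, deterministic re-runs, full provenance.

A pipeline run reads an image stack and nucleus ROIs, detects foci per
channel on the ROI-cleared volume, assigns them to nuclei, computes
relative gonad positions, classifies pairwise colocalization, scores axis
association, detects zones, and writes every stage's output as TSV/JSON
with the parameters and input hashes that produced it.  Identical config
and inputs yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from skimage.draw import polygon2mask

from . import assign as assign_mod
from . import axis as axis_mod
from . import coloc as coloc_mod
from . import io as io_mod
from . import zones as zones_mod
from .core import ChannelMeta, DetectionTable
from .detect import DetectionParams, find_maxima_3d

logger = logging.getLogger("gonadfoci")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated configuration of a full run (see ``from_json``)."""

    image: str
    rois: str
    channels: list[ChannelMeta]
    detection: dict  # channel -> DetectionParams
    spacing_nm: Optional[tuple] = None
    na: float = 1.4
    coloc_pairs: list = field(default_factory=list)  # (query, reference) channel names
    axis: Optional[dict] = None  # {channel, method, value?, dilate_z, foci_channel}
    region_x: Optional[tuple] = None
    peak_window: Optional[dict] = None  # {channel, width_rows, row_pitch?}
    out_dir: str = "out"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        channels = [ChannelMeta(c["name"], c["emission_nm"]) for c in raw["channels"]]
        detection = {
            ch: DetectionParams(**params) for ch, params in raw["detection"].items()
        }
        cfg = cls(
            image=raw["image"],
            rois=raw["rois"],
            channels=channels,
            detection=detection,
            spacing_nm=tuple(raw["spacing_nm"]) if raw.get("spacing_nm") else None,
            na=raw.get("na", 1.4),
            coloc_pairs=[tuple(p) for p in raw.get("coloc_pairs", [])],
            axis=raw.get("axis"),
            region_x=tuple(raw["region_x"]) if raw.get("region_x") else None,
            peak_window=raw.get("peak_window"),
            out_dir=raw.get("out_dir", "out"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        names = {c.name for c in self.channels}
        referenced = set(self.detection)
        for q, r in self.coloc_pairs:
            referenced |= {q, r}
        if self.axis:
            referenced.add(self.axis["channel"])
            referenced.add(self.axis.get("foci_channel", next(iter(self.detection), "")))
        if self.peak_window:
            referenced.add(self.peak_window["channel"])
        unknown = referenced - names
        if unknown:
            raise ValueError(f"config references unknown channels: {sorted(unknown)}")
        if self.spacing_nm is not None and any(s <= 0 for s in self.spacing_nm):
            raise ValueError("spacing must be positive")
        if self.na <= 0:
            raise ValueError("NA must be positive")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _roi_mask_2d(rois, shape_yx) -> np.ndarray:
    mask = np.zeros(shape_yx, dtype=bool)
    for r in rois:
        mask |= polygon2mask(shape_yx, np.asarray(r.polygon)[:, ::-1])
    return mask


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage and write the report bundle.

    Returns a dict of in-memory results keyed by stage.  Any stage failure
    aborts with :class:`PipelineError` naming the stage and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    provenance: dict = {
        "inputs": {},
        "parameters": {
            "na": config.na,
            "spacing_nm": config.spacing_nm,
            "detection": {
                ch: vars(p).copy() for ch, p in config.detection.items()
            },
            "coloc_pairs": [list(p) for p in config.coloc_pairs],
            "axis": config.axis,
            "region_x": list(config.region_x) if config.region_x else None,
            "peak_window": config.peak_window,
        },
    }

    def stage(name):
        def deco(fn):
            try:
                logger.info("stage=%s start", name)
                r = fn()
                logger.info("stage=%s done", name)
                return r
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, exc) from exc

        return deco

    @stage("read")
    def _read():
        stack = io_mod.read_stack(config.image, spacing=config.spacing_nm, channels=config.channels)
        rois = io_mod.read_rois(config.rois)
        provenance["inputs"] = {
            "image": {"path": config.image, "sha256": _sha256(Path(config.image))},
            "rois": {"path": config.rois, "sha256": _sha256(Path(config.rois))},
        }
        return stack, rois

    stack, rois = _read
    results["stack"], results["rois"] = stack, rois
    roi_mask = _roi_mask_2d(rois, stack.shape_zyx[1:])

    tables: dict[str, DetectionTable] = {}

    @stage("detect+assign")
    def _detect():
        for ch, params in sorted(config.detection.items()):
            foci = find_maxima_3d(stack, ch, params, mask=roi_mask)
            logger.info("stage=detect channel=%s n_foci=%d", ch, len(foci))
            table = assign_mod.assign_foci(foci, rois)
            table, report = assign_mod.resolve_overlaps(table, rois)
            if config.region_x:
                table = assign_mod.relative_positions(
                    table, rois, config.region_x[0], config.region_x[1]
                )
            table.provenance = {"channel": ch, "detection": vars(params).copy()}
            tables[ch] = table
            io_mod.write_detection_table(table, out / f"foci_{_safe(ch)}.tsv")
            if report:
                (out / f"overlaps_{_safe(ch)}.json").write_text(
                    json.dumps([vars(r) for r in report], indent=1, sort_keys=True)
                )
        return tables

    _detect
    results["tables"] = tables

    @stage("counts")
    def _counts():
        frames = []
        for ch, table in sorted(tables.items()):
            counts, unassigned = assign_mod.count_foci_per_nucleus(table)
            counts["unassigned_total"] = unassigned
            frames.append(counts)
        import pandas as pd

        allc = pd.concat(frames, ignore_index=True) if frames else None
        if allc is not None:
            allc.to_csv(out / "counts_per_nucleus.tsv", sep="\t", index=False)
        return allc

    results["counts"] = _counts

    @stage("coloc")
    def _coloc():
        reports = {}
        emission = {c.name: c.emission_nm for c in config.channels}
        for q, r in config.coloc_pairs:
            thr = coloc_mod.pair_threshold(emission[q], emission[r], config.na)
            records = coloc_mod.nearest_neighbor_classify(
                tables[q].to_foci(), tables[r].to_foci(), thr, reference_species=r
            )
            rel = {
                row.focus_id: row.rel_position_pct
                for row in tables[q].to_foci()
                if row.rel_position_pct is not None
            }
            rep = coloc_mod.coloc_report(records, rel_positions=rel)
            rep.insert(0, "threshold_nm", thr)
            rep.to_csv(
                out / f"coloc_{_safe(q)}_vs_{_safe(r)}.tsv",
                sep="\t", index=False, float_format="%.6f",
            )
            reports[(q, r)] = rep
        return reports

    results["coloc"] = _coloc

    if config.axis:
        @stage("axis")
        def _axis():
            spec = config.axis
            mask = axis_mod.build_axis_mask(
                stack, spec["channel"], method=spec.get("method", "otsu"),
                value=spec.get("value"),
            )
            mask = axis_mod.dilate_z(mask, int(spec.get("dilate_z", 1)))
            foci_ch = spec.get("foci_channel", next(iter(sorted(config.detection))))
            res = axis_mod.axis_association_fraction(tables[foci_ch].to_foci(), mask)
            payload = {
                "foci_channel": foci_ch,
                "associated": res.associated,
                "total": res.total,
                "fraction": res.fraction,
                "ci95": list(res.ci95),
                "mask_provenance": mask.provenance,
            }
            (out / "axis_association.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
            return res

        results["axis"] = _axis

    if config.peak_window:
        @stage("zones")
        def _zones():
            pw = config.peak_window
            ch = pw["channel"]
            zones_mod.assign_rows(rois, row_pitch=pw.get("row_pitch"))
            counts, _ = assign_mod.count_foci_per_nucleus(tables[ch])
            by_nuc = dict(zip(counts["nucleus_id"], counts["n_foci"]))
            rows, vals = [], []
            for r in rois:
                rows.append(r.row_index)
                vals.append(by_nuc.get(r.id, 0))
            zone = zones_mod.peak_window(vals, rows, width_rows=int(pw.get("width_rows", 10)))
            payload = {
                "channel": ch,
                "start_row": zone.start_row,
                "end_row": zone.end_row,
                "length_rows": zone.length_rows,
                "rule": zone.rule,
            }
            (out / "zones.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
            return zone

        results["zones"] = _zones

    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
    return results


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in name)
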