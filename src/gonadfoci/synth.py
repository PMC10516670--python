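"""Ground-truth-annotated synthetic gonad scenes.

Generates multi-channel 3D stacks that emulate the statistical structure of
spread / whole-mount germline images: nuclei arrayed in cell rows along the
gonad (x) axis, diffraction-limited foci of several species rendered as
anisotropic Gaussian spots, controlled pairwise colocalization and
chromosome-axis association fractions, curvilinear axis tracks, and
additive Gaussian background noise.  Every generative choice is recorded in
a GroundTruth object so each downstream stage can be scored against truth.

The generator states a world, not a photorealistic microscope: spots are
separable Gaussians truncated at 4 sigma placed at voxel centres, axis
tracks are smoothed random walks one voxel wide, and noise is i.i.d.
Gaussian.  Defaults emulate widefield imaging of C. elegans gonads: 200 nm
z-steps, 80 nm xy pixels, spot FWHM ~ 3 voxels in xy.

Determinism: one root RNG stream per scene seeded from ``spec.seed``;
per-nucleus sub-streams are derived as ``(seed, nucleus_index)`` so edits
to one part of a spec do not reshuffle the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .core import ChannelMeta, Focus, ImageStack, NucleusROI

DEFAULT_SPACING_NM = (200.0, 80.0, 80.0)  # widefield z-step, typical xy pixel
DEFAULT_PSF_SIGMA_VOX = (0.8, 1.3, 1.3)  # xy FWHM = 2.355*1.3 ~ 3 voxels
# two equal Gaussians with sigma_xy ~1.3 merge below ~3 voxels separation;
# 4 keeps every same-species pair bimodal on the grid
MIN_FOCUS_SEPARATION_VOX = 4.0
_PLACEMENT_ATTEMPTS = 500


@dataclass
class SpeciesParams:
    """Per-species focus statistics.

    ``n_foci`` is either a fixed count per nucleus or ``("poisson", mean)``;
    ``peak_height`` a fixed value or ``(mean, sd)`` of a truncated normal
    (>= 10% of mean).
    """

    n_foci: Union[int, tuple] = 5
    psf_sigma_vox: tuple[float, float, float] = DEFAULT_PSF_SIGMA_VOX
    peak_height: Union[float, tuple] = 1000.0
    emission_nm: float = 555.0


@dataclass
class ColocSpec:
    """True-colocalization structure between two species.

    A fraction of ``species_b`` foci are placed at ``offset_nm`` (rounded to
    the nearest voxel offset) from a focus of ``species_a``; the rest are
    rejection-sampled to lie farther than ``clearance_nm`` from every
    ``species_a`` focus, so ground truth is unambiguous at any threshold in
    between.  ``species_a`` must be generated before ``species_b``
    (dict order of ``species_params``).
    """

    species_a: str
    species_b: str
    fraction: float = 0.5
    offset_nm: float = 100.0
    clearance_nm: float = 600.0  # > 2x both 242 and 282 nm thresholds


@dataclass
class AxisSpec:
    """Chromosome-axis channel: curvilinear tracks inside each nucleus."""

    channel: str = "HTP-3"
    curves_per_nucleus: int = 2
    intensity: float = 800.0
    association_fraction: dict = field(default_factory=dict)  # species -> fraction
    off_axis_clearance_vox: float = 3.0


@dataclass
class SceneSpec:
    """Full description of one synthetic gonad field."""

    n_nuclei: int = 12
    # pachytene nuclei are ~4 um across: radius ~25 voxels at 80 nm xy pixels
    nucleus_radius_vox: float = 25.0
    rows: int = 2  # nuclei per cell row
    gonad_length_vox: Optional[int] = None  # derived from rows when None
    z_extent_vox: int = 8
    species_params: dict = field(default_factory=lambda: {"RAD-51": SpeciesParams()})
    coloc_spec: list = field(default_factory=list)
    axis_spec: Optional[AxisSpec] = None
    background_mean: float = 50.0
    background_sd: float = 10.0
    spacing_nm: tuple[float, float, float] = DEFAULT_SPACING_NM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0 or self.rows < 1:
            raise ValueError("n_nuclei must be >= 0 and rows >= 1")
        for cs in self.coloc_spec:
            if not 0.0 <= cs.fraction <= 1.0:
                raise ValueError("colocalization fractions must be in [0, 1]")
        if self.axis_spec:
            for f in self.axis_spec.association_fraction.values():
                if not 0.0 <= f <= 1.0:
                    raise ValueError("axis-association fractions must be in [0, 1]")


@dataclass
class TrueFocus:
    id: str
    species: str
    nucleus_id: str
    position_vox: tuple[int, int, int]
    position_nm: tuple[float, float, float]
    peak_height: float
    axis_associated: Optional[bool] = None
    partner_id: Optional[str] = None  # colocalized partner focus (other species)


@dataclass
class GroundTruth:
    """Everything the generator decided, for scoring downstream stages."""

    foci: list = field(default_factory=list)  # TrueFocus records
    pairs: list = field(default_factory=list)  # (id_a, id_b) colocalized pairs
    row_index: dict = field(default_factory=dict)  # nucleus_id -> cell row
    axis_voxels: dict = field(default_factory=dict)  # nucleus_id -> (N,3) voxel array
    realized_coloc: dict = field(default_factory=dict)  # (a, b) -> (k, n)
    realized_axis: dict = field(default_factory=dict)  # species -> (k, n)

    def foci_of(self, species: str) -> list:
        return [f for f in self.foci if f.species == species]

    def as_focus_objects(self, species: str) -> list[Focus]:
        return [
            Focus(
                id=f.id,
                species=f.species,
                position_vox=f.position_vox,
                position_nm=f.position_nm,
                peak_height=f.peak_height,
                nucleus_id=f.nucleus_id,
            )
            for f in self.foci_of(species)
        ]


# ---------------------------------------------------------------------------

def _draw_count(rng: np.random.Generator, n_foci) -> int:
    if isinstance(n_foci, (int, np.integer)):
        return int(n_foci)
    kind, mean = n_foci
    if kind != "poisson":
        raise ValueError(f"unknown focus-count distribution {kind!r}")
    return int(rng.poisson(mean))


def _draw_peak(rng: np.random.Generator, peak_height) -> float:
    if isinstance(peak_height, (int, float)):
        return float(peak_height)
    mean, sd = peak_height
    return float(max(rng.normal(mean, sd), 0.1 * mean))


def _nucleus_layout(spec: SceneSpec) -> tuple[tuple[int, int, int], list[dict]]:
    """Grid of nucleus centres: cell rows along x, ``spec.rows`` nuclei per row in y."""
    r = spec.nucleus_radius_vox
    pitch = int(math.ceil(2 * r + 3))
    n_rows = int(math.ceil(spec.n_nuclei / spec.rows)) if spec.n_nuclei else 1
    margin = pitch // 2 + 1
    nx = spec.gonad_length_vox or (2 * margin + n_rows * pitch)
    ny = 2 * margin + spec.rows * pitch
    nz = spec.z_extent_vox
    nuclei = []
    for k in range(spec.n_nuclei):
        row, j = divmod(k, spec.rows)
        cx = margin + (row + 0.5) * pitch
        cy = margin + (j + 0.5) * pitch
        nuclei.append({"id": f"n{k:03d}", "center_xy": (cx, cy), "row": row})
    return (nz, ny, nx), nuclei


def _circle_polygon(cx: float, cy: float, radius: float, n_vertices: int = 16) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([cx + radius * np.cos(th), cy + radius * np.sin(th)])


def _axis_curve(
    rng: np.random.Generator, center_xy, radius: float, nz: int
) -> np.ndarray:
    """A smoothed random-walk track inside the nucleus, one z plane, (N,3) voxels.

    Curves are confined to the low-x half of the nucleus (x <= cx - 2) so
    that off-axis foci can honour the xy clearance that keeps ground truth
    unambiguous; real axis signal fills the nucleus, but the generator
    trades that realism for a scorable world.
    """
    cx, cy = center_xy
    n_steps = max(int(3 * radius), 8)
    x_max = cx - 2.0
    ang = rng.uniform(0, 2 * np.pi)
    x = cx - 0.5 * radius + rng.uniform(-1.0, 1.0)
    y = cy + rng.uniform(-0.3, 0.3) * radius
    z = int(rng.integers(1, max(nz - 1, 2)))
    pts = []
    for _ in range(n_steps):
        pts.append((z, int(round(y)), int(round(x))))
        ang += rng.normal(0.0, 0.5)
        x_new, y_new = x + math.cos(ang), y + math.sin(ang)
        # reflect off the allowed region (inner disc, low-x half)
        if (x_new - cx) ** 2 + (y_new - cy) ** 2 > (0.85 * radius) ** 2 or x_new > x_max:
            ang += math.pi / 2
            x_new, y_new = x + math.cos(ang), y + math.sin(ang)
            if (x_new - cx) ** 2 + (y_new - cy) ** 2 > (0.85 * radius) ** 2 or x_new > x_max:
                x_new, y_new = x, y  # stay put this step
        x, y = x_new, y_new
    return np.unique(np.asarray(pts, dtype=int), axis=0)


def _render_spot(vol: np.ndarray, pos: tuple, sigma: tuple, peak: float) -> None:
    """Add a separable Gaussian of given peak, truncated at 4 sigma."""
    z0, y0, x0 = pos
    sz, sy, sx = sigma
    rz, ry, rx = (int(math.ceil(4 * s)) for s in sigma)
    zs = np.arange(max(z0 - rz, 0), min(z0 + rz + 1, vol.shape[0]))
    ys = np.arange(max(y0 - ry, 0), min(y0 + ry + 1, vol.shape[1]))
    xs = np.arange(max(x0 - rx, 0), min(x0 + rx + 1, vol.shape[2]))
    gz = np.exp(-0.5 * ((zs - z0) / sz) ** 2)
    gy = np.exp(-0.5 * ((ys - y0) / sy) ** 2)
    gx = np.exp(-0.5 * ((xs - x0) / sx) ** 2)
    vol[np.ix_(zs, ys, xs)] += peak * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


def _voxel_offset_for_nm(offset_nm: float, spacing: tuple) -> np.ndarray:
    """Integer (z, y, x) voxel offset whose physical length best matches offset_nm."""
    best, best_err = np.array([0, 0, 1]), np.inf
    sz, sy, sx = spacing
    for dz in range(0, 2):
        for dy in range(0, 3):
            for dx in range(0, 3):
                if dz == dy == dx == 0:
                    continue
                d = math.sqrt((dz * sz) ** 2 + (dy * sy) ** 2 + (dx * sx) ** 2)
                if abs(d - offset_nm) < best_err:
                    best, best_err = np.array([dz, dy, dx]), abs(d - offset_nm)
    return best


def generate_scene(spec: SceneSpec) -> tuple[ImageStack, list[NucleusROI], GroundTruth]:
    """Render a synthetic gonad field with full ground truth.

    Returns the multi-channel stack (one channel per species, plus the axis
    channel when requested), the nucleus ROI polygons, and the GroundTruth.
    Identical specs (same seed) produce bit-identical outputs.
    """
    shape_zyx, nuclei = _nucleus_layout(spec)
    nz, ny, nx = shape_zyx
    species = list(spec.species_params)
    channel_names = species + ([spec.axis_spec.channel] if spec.axis_spec else [])
    vols = {name: np.zeros(shape_zyx, dtype=np.float64) for name in channel_names}
    truth = GroundTruth()
    spacing = spec.spacing_nm
    coloc_by_target: dict[str, ColocSpec] = {}
    for cs in spec.coloc_spec:
        if cs.species_a not in species or cs.species_b not in species:
            raise ValueError(f"coloc spec references unknown species {cs.species_a}/{cs.species_b}")
        if species.index(cs.species_a) >= species.index(cs.species_b):
            raise ValueError("coloc_spec: species_a must precede species_b in species_params")
        coloc_by_target[cs.species_b] = cs

    rois = []
    axis_assoc_counts: dict[str, list[int]] = {s: [0, 0] for s in species}
    coloc_counts: dict[tuple, list[int]] = {
        (cs.species_a, cs.species_b): [0, 0] for cs in spec.coloc_spec
    }

    def vox_to_nm(p):
        return tuple((float(v) + 0.5) * s for v, s in zip(p, spacing))

    for k, nuc in enumerate(nuclei):
        rng = np.random.default_rng([spec.seed, k])
        cx, cy = nuc["center_xy"]
        radius = spec.nucleus_radius_vox
        rois.append(NucleusROI(id=nuc["id"], polygon=_circle_polygon(cx, cy, radius)))
        truth.row_index[nuc["id"]] = nuc["row"]

        axis_vox = np.zeros((0, 3), dtype=int)
        if spec.axis_spec:
            curves = [
                _axis_curve(rng, (cx, cy), radius, nz)
                for _ in range(spec.axis_spec.curves_per_nucleus)
            ]
            if curves:
                axis_vox = np.unique(np.concatenate(curves), axis=0)
            for z, y, x in axis_vox:
                vols[spec.axis_spec.channel][z, y, x] += spec.axis_spec.intensity
            truth.axis_voxels[nuc["id"]] = axis_vox

        placed: dict[str, list[np.ndarray]] = {s: [] for s in species}

        def _sample_position(sp_name: str, want_axis: Optional[bool]) -> Optional[np.ndarray]:
            for _ in range(_PLACEMENT_ATTEMPTS):
                if want_axis and len(axis_vox):
                    pos = axis_vox[rng.integers(len(axis_vox))].copy()
                else:
                    ang = rng.uniform(0, 2 * np.pi)
                    rr = 0.75 * radius * math.sqrt(rng.uniform())
                    pos = np.array(
                        [
                            rng.integers(1, max(nz - 1, 2)),
                            int(round(cy + rr * math.sin(ang))),
                            int(round(cx + rr * math.cos(ang))),
                        ]
                    )
                if want_axis is False and len(axis_vox):
                    dxy = axis_vox[:, 1:] - pos[1:]
                    clear = spec.axis_spec.off_axis_clearance_vox
                    if (np.hypot(dxy[:, 0], dxy[:, 1]) < clear).any():
                        continue
                if any(
                    np.linalg.norm(pos - q) < MIN_FOCUS_SEPARATION_VOX
                    for q in placed[sp_name]
                ):
                    continue
                if not (0 <= pos[0] < nz and 0 <= pos[1] < ny and 0 <= pos[2] < nx):
                    continue
                return pos
            return None

        for sp_name in species:
            sp = spec.species_params[sp_name]
            n = _draw_count(rng, sp.n_foci)
            cs = coloc_by_target.get(sp_name)
            assoc_frac = (
                spec.axis_spec.association_fraction.get(sp_name) if spec.axis_spec else None
            )
            for i in range(n):
                partner = None
                want_axis: Optional[bool] = None
                if assoc_frac is not None:
                    want_axis = bool(rng.uniform() < assoc_frac)
                pos = None
                if cs is not None:
                    is_pair = rng.uniform() < cs.fraction
                    all_a = truth.foci_of(cs.species_a)
                    partners = [f for f in all_a if f.nucleus_id == nuc["id"]]
                    if is_pair and partners:
                        off = _voxel_offset_for_nm(cs.offset_nm, spacing)
                        for _ in range(_PLACEMENT_ATTEMPTS):
                            ref = partners[int(rng.integers(len(partners)))]
                            sign = rng.choice([-1, 1], size=3)
                            cand = np.asarray(ref.position_vox) + off * sign
                            if not (
                                0 <= cand[0] < nz
                                and 0 <= cand[1] < ny
                                and 0 <= cand[2] < nx
                            ):
                                continue
                            if any(
                                np.linalg.norm(cand - q) < MIN_FOCUS_SEPARATION_VOX
                                for q in placed[sp_name]
                            ):
                                continue
                            pos, partner = cand, ref.id
                            break
                    else:
                        # stay clear of every partner-species focus, any nucleus
                        for _ in range(_PLACEMENT_ATTEMPTS):
                            p = _sample_position(sp_name, want_axis)
                            if p is None:
                                break
                            p_nm = np.asarray(vox_to_nm(p))
                            if all(
                                np.linalg.norm(p_nm - np.asarray(f.position_nm))
                                > cs.clearance_nm
                                for f in all_a
                            ):
                                pos = p
                                break
                else:
                    pos = _sample_position(sp_name, want_axis)
                if pos is None:
                    raise ValueError(
                        f"could not place focus {i} of {sp_name} in nucleus {nuc['id']}: "
                        "foci per nucleus infeasible for nucleus size"
                    )
                pos = tuple(int(v) for v in pos)
                placed[sp_name].append(np.asarray(pos))
                if cs is not None:
                    coloc_counts[(cs.species_a, cs.species_b)][1] += 1
                    if partner is not None:
                        coloc_counts[(cs.species_a, cs.species_b)][0] += 1
                peak = _draw_peak(rng, sp.peak_height)
                _render_spot(vols[sp_name], pos, sp.psf_sigma_vox, peak)
                on_axis = None
                if spec.axis_spec and sp_name in spec.axis_spec.association_fraction:
                    on_axis = bool(
                        len(axis_vox)
                        and (np.all(axis_vox == np.asarray(pos), axis=1)).any()
                    )
                    axis_assoc_counts[sp_name][0] += int(on_axis)
                    axis_assoc_counts[sp_name][1] += 1
                fid = f"{sp_name}:{nuc['id']}:{i}"
                tf = TrueFocus(
                    id=fid,
                    species=sp_name,
                    nucleus_id=nuc["id"],
                    position_vox=pos,
                    position_nm=vox_to_nm(pos),
                    peak_height=peak,
                    axis_associated=on_axis,
                    partner_id=partner,
                )
                truth.foci.append(tf)
                if partner is not None:
                    truth.pairs.append((partner, fid))

    root = np.random.default_rng(spec.seed)
    if spec.background_sd > 0 or spec.background_mean > 0:
        for name in channel_names:
            noise = root.normal(spec.background_mean, spec.background_sd, size=shape_zyx)
            vols[name] = np.maximum(vols[name] + noise, 0.0)

    for pair, (k_, n_) in coloc_counts.items():
        truth.realized_coloc[pair] = (k_, n_)
    for sp_name, (k_, n_) in axis_assoc_counts.items():
        if n_:
            truth.realized_axis[sp_name] = (k_, n_)

    channels = [
        ChannelMeta(name=s, emission_nm=spec.species_params[s].emission_nm) for s in species
    ]
    if spec.axis_spec:
        channels.append(ChannelMeta(name=spec.axis_spec.channel, emission_nm=617.0))
    stack = ImageStack(
        voxels=np.stack([vols[c.name] for c in channels]),
        spacing=spacing,
        channels=channels,
    )
    return stack, rois, truth


# ---------------------------------------------------------------------------
# synthetic chromosome traces

@dataclass
class TraceTruth:
    trace_id: str
    length_um: float
    is_fusion: bool
    co_arc_fractions: list  # planted positions as fractions of arc length
    co_rel_positions: list  # min(f, 1-f) — the value the analysis should recover


def _random_polyline(rng: np.random.Generator, target_length_um: float, n_points: int = 200) -> np.ndarray:
    """A smooth random 3D curve rescaled to the exact target arc length."""
    steps = rng.normal(size=(n_points - 1, 3))
    # momentum smoothing keeps curvature gentle, like a traced chromosome
    for i in range(1, len(steps)):
        steps[i] = 0.8 * steps[i - 1] + 0.2 * steps[i]
    norms = np.linalg.norm(steps, axis=1)
    norms[norms == 0] = 1.0
    steps = steps / norms[:, None]
    pts = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
    length = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
    return pts * (target_length_um / length)


def generate_trace_set(
    n_traces: int,
    length_range_um: tuple[float, float] = (4.0, 10.0),
    fusion_length_range_um: tuple[float, float] = (16.0, 25.0),
    fusion_fraction: float = 0.0,
    co_sites_per_trace: int = 1,
    seed: int = 0,
    n_points: int = 200,
):
    """Random chromosome traces with CO sites planted at known arc fractions.

    Fusion traces draw their length from ``fusion_length_range_um`` (all
    above the 15 μm cutoff); the rest from ``length_range_um``.  CO points
    are interpolated exactly onto the polyline, so the analysis should
    recover ``min(f, 1-f)`` up to float precision.
    """
    from .traces import ChromosomeTrace

    if length_range_um[0] <= 0:
        raise ValueError("lengths must be > 0")
    rng = np.random.default_rng(seed)
    traces, truths = [], []
    for t in range(n_traces):
        is_fusion = bool(rng.uniform() < fusion_fraction)
        lo, hi = fusion_length_range_um if is_fusion else length_range_um
        length = float(rng.uniform(lo, hi))
        pts = _random_polyline(rng, length, n_points=n_points)
        seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        fracs = sorted(float(f) for f in rng.uniform(0.05, 0.95, size=co_sites_per_trace))
        cos = []
        for f in fracs:
            s = f * cum[-1]
            i = int(np.searchsorted(cum, s, side="right")) - 1
            i = min(i, len(seg_len) - 1)
            tloc = (s - cum[i]) / seg_len[i]
            cos.append(pts[i] + tloc * (pts[i + 1] - pts[i]))
        trace = ChromosomeTrace(
            id=f"tr{t:03d}", points_um=pts, co_sites_um=np.asarray(cos).reshape(-1, 3)
        )
        traces.append(trace)
        truths.append(
            TraceTruth(
                trace_id=trace.id,
                length_um=length,
                is_fusion=length > 15.0,
                co_arc_fractions=fracs,
                co_rel_positions=[min(f, 1.0 - f) for f in fracs],
            )
        )
    return traces, truths


# ---------------------------------------------------------------------------
# synthetic staging profiles (row-level, no imaging)

def generate_row_flags(
    n_rows: int,
    nuclei_per_row: int,
    zone: tuple[int, int],
    frac_in: float = 0.8,
    frac_out: float = 0.2,
    seed: int = 0,
) -> tuple[list[int], list[bool]]:
    """Per-nucleus staining flags with an exact majority inside ``zone``.

    Within the zone exactly ``round(frac_in * nuclei_per_row)`` nuclei per
    row are flagged (and ``frac_out`` outside), so the majority-rule zone is
    deterministic; the RNG only shuffles which nuclei carry the flag.
    """
    rng = np.random.default_rng(seed)
    rows, flags = [], []
    for r in range(n_rows):
        frac = frac_in if zone[0] <= r <= zone[1] else frac_out
        k = int(round(frac * nuclei_per_row))
        fl = np.zeros(nuclei_per_row, dtype=bool)
        fl[:k] = True
        rng.shuffle(fl)
        rows.extend([r] * nuclei_per_row)
        flags.extend(bool(v) for v in fl)
    return rows, flags


def generate_staging_counts(
    n_rows: int,
    nuclei_per_row: int,
    start_row: int,
    end_row: int,
    seed: int = 0,
) -> tuple[list[int], list[int], list[int]]:
    """Per-nucleus RAD-51 and CO-site (MSH-5) counts with known zone bounds.

    Most nuclei have >= 1 RAD-51 focus from ``start_row`` on, and exactly 6
    MSH-5 foci from ``end_row`` on; majorities are exact so the recovered
    early-pachytene zone equals (start_row, end_row).
    Returns (rows, rad51_counts, msh5_counts).
    """
    rng = np.random.default_rng(seed)
    rows, rad51, msh5 = [], [], []
    k_major = int(round(0.8 * nuclei_per_row))
    k_minor = nuclei_per_row // 5
    for r in range(n_rows):
        has_rad = np.zeros(nuclei_per_row, dtype=bool)
        has_six = np.zeros(nuclei_per_row, dtype=bool)
        has_rad[: k_major if r >= start_row else k_minor] = True
        if r >= end_row:
            has_six[:k_major] = True
        rng.shuffle(has_rad)
        rng.shuffle(has_six)
        for i in range(nuclei_per_row):
            rows.append(r)
            rad51.append(int(rng.integers(1, 5)) if has_rad[i] else 0)
            msh5.append(6 if has_six[i] else int(rng.integers(0, 6)))
    return rows, rad51, msh5
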