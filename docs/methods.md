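# Methods

This note documents the models, conventions and design choices behind
`gonadfoci`, in the spirit of the methods documentation of statsmodels or
scanpy: what each stage computes, under which assumptions, and what a green
test does and does not establish.

## Coordinates and units

Volumes are indexed `(channel, z, y, x)`. Physical voxel spacing is given
in nanometres as `(z, y, x)`; the default synthetic spacing is
`(200, 80, 80)` nm — a 200 nm z-step typical of widefield germline imaging
and an 80 nm xy pixel typical of a 60×/NA 1.4 system. Voxel `i` is centred
at `(i + 0.5) · spacing` (voxel-centre convention), so distances between
adjacent voxel centres equal the spacing, and `vox → nm → vox` is exact.
Chromosome traces are in μm.

## Focus detection

A focus is a filtered 3D local maximum, following the 3D Maxima Finder
parameterization:

1. intensity ≥ `min_peak_height`;
2. local maximum (ties allowed) within the anisotropic ellipsoid
   `(dz/r_z)² + (dy/r_xy)² + (dx/r_xy)² ≤ 1`, radii in voxels,
   defaults `r_xy = r_z = 1.5`;
3. prominence ≥ `noise` (default 100 intensity units), where prominence is
   the peak intensity minus the minimum over the shell between the 1× and
   2× ellipsoids (out-of-bounds shell voxels are ignored);
4. among surviving candidates within one neighborhood of each other, only
   the brightest is kept; ties break to the smallest (z, y, x), which also
   collapses plateau maxima to one call.

The "Noise" semantics of the original plugin are not publicly specified;
the shell-prominence criterion was chosen because it is a standard
prominence measure, monotone in the parameter, and directly checkable by a
brute-force oracle. The criterion is isolated in one place so an
alternative (e.g. flood-based prominence) can be swapped in.

`min_peak_height` has no universal default: it is calibrated per image
starting from the maximum intensity over operator-chosen background regions
(`calibrate_min_peak_height`) and refined empirically. Out-of-ROI signal is
cleared before detection when a mask is supplied, mirroring the ROI-cleared
volumes the original counts were computed from.

Properties established by tests: exact equivalence with a brute-force
evaluation of rules 1–4 on random volumes; invariance under intensity
translation (with the peak threshold shifted alongside; prominence is
translation-invariant so `noise` is not shifted); monotone non-increasing
counts in both `min_peak_height` and `noise`; recall and precision ≥ 0.95
on synthetic scenes at SNR ≥ 10 with default radii and noise.

## Nucleus assignment and gonad position

Assignment is point-in-polygon on the focus's (x, y) — max projection
preserves xy, so testing the 3D maximum's xy against the 2D ROI is
equivalent to assigning from projections. The test is boundary-inclusive so
no focus is lost on shared edges. Foci inside several (overlapping) ROIs
are resolved to the nearest ROI centroid, ties to the smaller ROI id, and
every resolution is reported for review — a deterministic, auditable
stand-in for what was originally a manual check.

Relative gonad position is `100 · (centroid_x − x_start)/(x_end −
x_start)` using the nucleus centroid's x, 0% at the distal end of the
quantified region; the gonad's curvature is not unbent (linear x stands in
for arc position, as in the source workflow). Centroids outside the region
clamp to [0, 100] with a warning.

## Colocalization

Object-based and directional: each query focus is classified by the 3D
Euclidean distance (nm, voxel-centre coordinates, no z-collapse) to its
nearest neighbor in the reference species; colocalized iff that distance is
strictly under the threshold ("under" is read as strict; an exact tie is
not colocalized). The threshold is the Rayleigh resolution limit
`0.61 λ / NA` — 242 nm (λ = 555) and 282 nm (λ = 647) at NA = 1.4 — kept
exact by default, with the integer-rounded value available for reporting.
For a two-channel pair the redder channel's wavelength sets the threshold
(the pair is resolution-limited by the worse-resolved channel);
configurable per pair. Three-species categories (solo / +X / +Y / +X+Y)
come from independent pairwise tests, so per-species categories always
partition the species' foci.

Fractions are reported with Wilson score 95% intervals (well-behaved at
extreme fractions; Clopper–Pearson available). The confidence-interval
method was not specified upstream; Wilson is this package's choice.

## Axis association

The axis-protein channel is thresholded (fixed value or Otsu) into a
binary mask; the exact upstream mask recipe is external to this package, so
provenance (method, threshold, dilation) is recorded with every mask and
the construction is pluggable. The mask is dilated ±1 voxel in z only — xy
is untouched — to capture foci adjacent or tethered to the axis across the
coarser z-sampling. A focus is axis-associated iff the mask is true at its
maximum's voxel; the association fraction is associated/total with a Wilson
CI, and genotype contrasts use Fisher's exact test on the 2×2 counts.

## Zones and statistics

"Cell row" is operationalized as a bin of nucleus-centroid x positions of
fixed pitch (default: median nearest-neighbor centroid spacing along x,
after rounding away float noise); the original reading of rows was by eye.
"Majority" is strictly > 50% of the nuclei in a row. Zone rules:

- **majority zone** (CHK-2 active zone): longest contiguous run of
  majority-positive rows; ties to the earliest (most distal) run.
- **count-rule boundaries** (early/late pachytene): start at the first row
  where most nuclei satisfy the start predicate (e.g. ≥ 1 RAD-51 focus),
  end at the first subsequent row where most satisfy the end predicate
  (e.g. exactly 6 MSH-5/HIM-6 foci); unmet rules raise explicit errors.
- **peak window**: the 10-row window maximizing the median per-nucleus
  count; ties to the earliest window.

Group comparisons delegate to scipy (Mann–Whitney U, Welch's t, Fisher
exact; all two-sided), as these are standard procedures, not contributions
of this package. Brood viability follows the egg-count bookkeeping: total
eggs = max(eggs at 24 h, eggs at 48 h, adults at 72–96 h) — whichever is
larger, absorbing undercounting of young larvae — then
% hatching = 100·(1 − unhatched/total), % adulthood = 100·adults/total,
% males = 100·males/adults.

## Chromosome traces

Arc length is the sum of consecutive-point distances. A crossover site is
snapped to the nearest point on the polyline (default tolerance 0.5 μm;
farther points are errors, not silently included) and reported as arc
distance to the nearer end divided by total length — in [0, 0.5] by
construction and invariant under reversing the polyline. Chromosomes longer
than 15 μm (strict) are classified as fusion (mnT12) chromosomes. The CO
position histogram uses 10 bins over [0, 0.5] by default (the bin count was
not fixed upstream) and normalizes within each fusion class.

## The synthetic world

The generator states a world; it is not tuned to make tests pass:

- nuclei on a row grid along x, radius 25 voxels (~4 μm pachytene nuclei at
  80 nm pixels), `rows` nuclei per cell row;
- foci as separable Gaussians truncated at 4σ, σ = (0.8, 1.3, 1.3) voxels
  (xy FWHM ≈ 3 voxels, diffraction-limited widefield spots at the scale the
  default 1.5-voxel detection radii operate on), placed at voxel centres;
- same-species foci at least 4 voxels apart — two equal σ_xy ≈ 1.3
  Gaussians merge into a single maximum below ≈ 3 voxels separation, so
  this floor keeps every rendered spot individually callable;
- colocalized partners offset ~100 nm (nearest voxel offset; below both 242
  and 282 nm thresholds), non-partners rejection-sampled > 600 nm (beyond
  2× both thresholds) from every partner-species focus, making ground truth
  unambiguous at any threshold in between;
- axis tracks as smoothed random walks one voxel wide, confined to the
  low-x half of each nucleus so off-axis foci can honour a 3-voxel xy
  clearance — real axis signal pervades the nucleus; the generator trades
  that realism for scorable truth;
- additive i.i.d. Gaussian background (default mean 50, sd 10), clipped at
  zero, added after all structures;
- determinism: a root RNG per scene plus per-nucleus sub-streams derived
  from `(seed, nucleus_index)`, so identical specs are bit-identical and
  local spec edits do not reshuffle unrelated nuclei.

Not emulated: optical PSF tails and asymmetries, SIM reconstruction
artefacts, autofluorescence structure, nucleus shape irregularity, gonad
curvature, z-dependent attenuation. A green recovery test therefore
establishes the correctness of the pipeline's logic on data matching its
assumptions — not performance on real micrographs, where thresholds must be
calibrated per image.

Synthetic traces are momentum-smoothed random 3D walks rescaled to an exact
target length (discretization error < 1% by construction), with CO sites
interpolated exactly onto the polyline at known arc fractions; fusion
traces draw lengths from (16, 25) μm, non-fusion from (4, 10) μm.

## Numerical conventions and edge cases

- Strict inequalities where the upstream wording says "under" / "longer
  than" (colocalization threshold, 15 μm fusion cutoff); exact ties fall on
  the non-colocalized / non-fusion side.
- Tie-breaks are always deterministic and documented: lexicographic voxel
  order in detection, smaller ROI id in overlap resolution, earliest
  run/window in zones.
- Empty inputs are explicit: empty reference species ⇒ infinite distances,
  none colocalized; zero totals ⇒ empty report rows, not NaN arithmetic;
  unmet zone rules raise rather than return sentinels.
- Detection-table TSVs round-trip losslessly (repr-precision floats,
  UTF-8, tab delimiter, '.' decimal).
- Pipeline runs are byte-deterministic: fixed float formats, sorted JSON
  keys, and input hashes recorded in `provenance.json`.

## Known limitations

- The "Noise" criterion is this package's interpretation (shell
  prominence); counts can differ from the original plugin's on real data.
- The axis-mask recipe is a labelled stand-in (fixed/Otsu threshold), not
  the exact upstream procedure.
- Linear x-position staging ignores gonad curvature.
- No sub-voxel localization or spot-shape fitting; positions are voxel
  maxima.
- The automated overlap resolution approximates a manual review; the
  report exists precisely so a human can override it.
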