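"""3D maxima detection against a brute-force post-condition oracle."""

import numpy as np
import pytest

from gonadfoci.core import NucleusROI
from gonadfoci.detect import DetectionParams, calibrate_min_peak_height, find_maxima_3d

from conftest import render_spot, single_channel_stack


def brute_force_maxima(vol, params):
    """Direct evaluation of the calling rules at every voxel (independent oracle).

    Pure-python loops: candidate iff intensity >= min_peak_height, >= every
    in-bounds neighbor in the ellipsoid, and prominence over the in-bounds
    shell minimum >= noise; then brightest-first greedy suppression with
    ties to the smallest (z, y, x).
    """
    nz, ny, nx = vol.shape
    rz, rxy = params.radius_z, params.radius_xy

    def offsets(scale):
        out = []
        for dz in range(-int(rz * scale), int(rz * scale) + 1):
            for dy in range(-int(rxy * scale), int(rxy * scale) + 1):
                for dx in range(-int(rxy * scale), int(rxy * scale) + 1):
                    if (dz, dy, dx) == (0, 0, 0):
                        continue
                    if (dz / (rz * scale)) ** 2 + (dy / (rxy * scale)) ** 2 + (
                        dx / (rxy * scale)
                    ) ** 2 <= 1.0 + 1e-12:
                        out.append((dz, dy, dx))
        return out

    core = offsets(1.0)
    shell = [o for o in offsets(2.0) if o not in set(core)]
    cands = []
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = vol[z, y, x]
                if v < params.min_peak_height:
                    continue
                ok = True
                for dz, dy, dx in core:
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx and vol[zz, yy, xx] > v:
                        ok = False
                        break
                if not ok:
                    continue
                if shell:
                    svals = [
                        vol[z + dz, y + dy, x + dx]
                        for dz, dy, dx in shell
                        if 0 <= z + dz < nz and 0 <= y + dy < ny and 0 <= x + dx < nx
                    ]
                    if not svals or v - min(svals) < params.noise:
                        continue
                cands.append((z, y, x, v))
    cands.sort(key=lambda c: (-c[3], c[0], c[1], c[2]))
    kept = []
    for z, y, x, v in cands:
        if all(
            (z - kz) ** 2 / rz**2 + (y - ky) ** 2 / rxy**2 + (x - kx) ** 2 / rxy**2
            > 1.0 + 1e-12
            for kz, ky, kx, _ in kept
        ):
            kept.append((z, y, x, v))
    return sorted((z, y, x) for z, y, x, _ in kept)


class TestExamples:
    def test_single_spot_noiseless(self):
        vol = render_spot((8, 16, 16), (4, 8, 8), peak=1000.0)
        stack = single_channel_stack(vol)
        foci = find_maxima_3d(stack, "RAD-51", DetectionParams(min_peak_height=500))
        assert len(foci) == 1
        assert foci[0].position_vox == (4, 8, 8)
        assert foci[0].peak_height == pytest.approx(1000.0)
        assert foci[0].position_nm == (4.5 * 200, 8.5 * 80, 8.5 * 80)

    def test_two_spots_one_voxel_apart_merge_to_brighter(self):
        vol = render_spot((8, 16, 16), (4, 8, 8), peak=1000.0)
        vol += render_spot((8, 16, 16), (4, 8, 9), peak=800.0)
        stack = single_channel_stack(vol)
        foci = find_maxima_3d(stack, "RAD-51", DetectionParams(min_peak_height=500))
        assert len(foci) == 1
        assert foci[0].position_vox == (4, 8, 8)
        oracle = brute_force_maxima(stack.channel("RAD-51"),
                                    DetectionParams(min_peak_height=500))
        assert [f.position_vox for f in foci] == oracle

    def test_uniform_below_threshold(self):
        stack = single_channel_stack(np.full((4, 8, 8), 50.0))
        foci = find_maxima_3d(stack, "RAD-51", DetectionParams(min_peak_height=100))
        assert foci == []

    def test_mask_clears_outside(self):
        vol = render_spot((8, 16, 16), (4, 3, 3), peak=1000.0)
        vol += render_spot((8, 16, 16), (4, 12, 12), peak=1000.0)
        stack = single_channel_stack(vol)
        mask = np.zeros((16, 16), dtype=bool)
        mask[:8, :8] = True
        foci = find_maxima_3d(stack, "RAD-51", DetectionParams(min_peak_height=500), mask=mask)
        assert [f.position_vox for f in foci] == [(4, 3, 3)]

    def test_mask_shape_mismatch(self):
        stack = single_channel_stack(np.zeros((4, 8, 8)))
        with pytest.raises(ValueError, match="mask shape"):
            find_maxima_3d(stack, "RAD-51", DetectionParams(min_peak_height=1),
                           mask=np.ones((5, 5), bool))


class TestOracleEquivalence:
    @pytest.mark.parametrize("radius", [1.0, 1.5, 2.0])
    def test_random_volumes(self, radius):
        """Exact match with the brute-force oracle on random <=16^3 volumes."""
        rng = np.random.default_rng(42)
        for trial in range(34):
            shape = tuple(rng.integers(5, 13, size=3))
            vol = rng.integers(0, 40, size=shape).astype(float) * 10.0
            params = DetectionParams(
                min_peak_height=float(rng.integers(5, 30) * 10),
                radius_xy=radius,
                radius_z=radius,
                noise=float(rng.integers(0, 15) * 10),
            )
            stack = single_channel_stack(vol)
            got = sorted(f.position_vox for f in find_maxima_3d(stack, "RAD-51", params))
            expected = brute_force_maxima(vol, params)
            assert got == expected, f"trial {trial} shape {shape} params {params}"


class TestProperties:
    def test_translation_invariance(self):
        """Shifting intensities and min_peak_height by c leaves calls unchanged.

        Prominence is translation-invariant, so 'noise' needs no shift.
        """
        rng = np.random.default_rng(7)
        vol = rng.integers(0, 50, size=(6, 10, 10)).astype(float) * 10
        p0 = DetectionParams(min_peak_height=200.0, noise=50.0)
        p1 = DetectionParams(min_peak_height=200.0 + 300.0, noise=50.0)
        a = find_maxima_3d(single_channel_stack(vol), "RAD-51", p0)
        b = find_maxima_3d(single_channel_stack(vol + 300.0), "RAD-51", p1)
        assert [f.position_vox for f in a] == [f.position_vox for f in b]

    @pytest.mark.parametrize("param", ["min_peak_height", "noise"])
    def test_count_monotone_nonincreasing(self, param):
        rng = np.random.default_rng(3)
        vol = rng.integers(0, 100, size=(6, 12, 12)).astype(float) * 10
        counts = []
        for v in [0, 100, 300, 500, 800]:
            kw = {"min_peak_height": 100.0, "noise": 50.0}
            kw[param] = float(v)
            counts.append(
                len(find_maxima_3d(single_channel_stack(vol), "RAD-51", DetectionParams(**kw)))
            )
        assert counts == sorted(counts, reverse=True)

    def test_synthetic_scene_recall_precision(self, demo_scene):
        """On the rendered demo scene every true focus is recovered within 1 voxel."""
        spec, (stack, rois, truth) = demo_scene
        for species in ("RAD-51", "MSH-5"):
            foci = find_maxima_3d(stack, species, DetectionParams(min_peak_height=300))
            tpos = np.array([f.position_vox for f in truth.foci_of(species)])
            hits = sum(
                1 for f in foci
                if (np.abs(tpos - np.array(f.position_vox)).max(axis=1) <= 1).any()
            )
            assert len(foci) == len(tpos)
            assert hits == len(foci)


class TestCalibration:
    def test_background_max(self):
        vol = np.full((4, 16, 16), 40.0)
        vol[:, 8:, 8:] = 55.0
        stack = single_channel_stack(vol)
        roi_a = NucleusROI(id="a", polygon=[[0, 0], [6, 0], [6, 6], [0, 6]])
        roi_b = NucleusROI(id="b", polygon=[[9, 9], [14, 9], [14, 14], [9, 14]])
        assert calibrate_min_peak_height(stack, "RAD-51", [roi_a]) == 40.0
        assert calibrate_min_peak_height(stack, "RAD-51", [roi_a, roi_b]) == 55.0

    def test_roi_over_spot_returns_spot_peak(self):
        # documented misuse: a background ROI covering a real spot
        vol = render_spot((6, 16, 16), (3, 8, 8), peak=900.0) + 40.0
        stack = single_channel_stack(vol)
        roi = NucleusROI(id="bad", polygon=[[4, 4], [12, 4], [12, 12], [4, 12]])
        assert calibrate_min_peak_height(stack, "RAD-51", [roi]) >= 900.0

    def test_empty_roi_set(self, tiny_stack):
        with pytest.raises(ValueError):
            calibrate_min_peak_height(tiny_stack, "RAD-51", [])
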