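"""Quantitative-phase feature tests: thickness, segmentation, per-cell
biophysics, MIP and the flow pipeline."""

import math

import numpy as np
import pytest
from skimage import draw

import holoqpi as h
from holoqpi.qpi import (
    CELLS_IN_DMEM,
    cell_features,
    fit_spherical_cap,
    flow_pipeline,
    label_and_filter,
    max_thickness,
    mip,
    otsu_segment,
    otsu_threshold,
    refine_cell_mask,
    thickness_map,
    three_bar_contrast,
)
from holoqpi.simulate import FlowSpec, flow_scene


def interclass_variance(img, t, nbins=256):
    """Inter-class variance of the 256-bin histogram split at threshold t."""
    counts, edges = np.histogram(img.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    lo = centers <= t
    w0, w1 = counts[lo].sum(), counts[~lo].sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = (counts[lo] * centers[lo]).sum() / w0
    mu1 = (counts[~lo] * centers[~lo]).sum() / w1
    return w0 * w1 * (mu0 - mu1) ** 2


def brute_force_otsu(img, nbins=256):
    """Independent oracle: exhaustive inter-class-variance maximisation.

    Returns (threshold, maximal variance); inside an empty histogram
    valley the threshold is ambiguous but the objective value is not.
    """
    counts, edges = np.histogram(img.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best_t, best_v = centers[0], -1.0
    for i in range(1, nbins):
        v = interclass_variance(img, centers[i - 1], nbins)
        if v > best_v:
            best_v, best_t = v, centers[i - 1]
    return best_t, best_v


class TestThickness:
    def test_bead_phase_to_diameter(self):
        """4.304 rad at 515 nm with Δn = 0.036 is a 9.8 µm path."""
        d = thickness_map(np.array([[4.3043]]), 515e-9, 0.036)
        assert d[0, 0] == pytest.approx(9.8e-6, rel=1e-3)

    def test_zero_phase_zero_thickness(self):
        np.testing.assert_array_equal(thickness_map(np.zeros((4, 4)), 515e-9, 0.03),
                                      np.zeros((4, 4)))

    def test_linearity(self):
        phi = np.random.default_rng(0).random((16, 16))
        np.testing.assert_allclose(
            thickness_map(2 * phi, 515e-9, 0.036),
            2 * thickness_map(phi, 515e-9, 0.036),
        )

    def test_zero_contrast_rejected(self):
        with pytest.raises(ZeroDivisionError):
            thickness_map(np.ones((4, 4)), 515e-9, 0.0)


class TestMaxThickness:
    def test_uniform_plateau(self):
        d = np.full((20, 20), 3.3e-6)
        m, s = max_thickness(d, k=10)
        assert m == pytest.approx(3.3e-6)
        assert s == 0.0

    def test_k_one_is_global_max(self):
        d = np.arange(100, dtype=float).reshape(10, 10)
        m, s = max_thickness(d, k=1)
        assert m == 99.0
        assert s == 0.0

    def test_small_object_rejected(self):
        d = np.ones((5, 5))
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        with pytest.raises(ValueError):
            max_thickness(d, mask=mask, k=10)


class TestOtsu:
    def test_two_level_image(self):
        img = np.zeros(1000)
        img[:100] = 4.0
        t = otsu_threshold(img)
        assert 0.0 < t < 4.0
        mask = otsu_segment(img.reshape(25, 40))
        assert mask.sum() == 100

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_maximiser(self, seed):
        """Oracle equivalence: same segmentation as exhaustive maximisation.

        Inside an empty histogram valley every split maximises the
        inter-class variance, so thresholds may differ by tie-breaking;
        the resulting masks must be identical.
        """
        rng = np.random.default_rng(seed)
        img = np.concatenate([
            rng.normal(0.0, 0.3, 2000),
            rng.normal(3.0, 0.6, rng.integers(100, 1500)),
        ])
        t = otsu_threshold(img)
        t_brute, v_brute = brute_force_otsu(img)
        assert interclass_variance(img, t) == pytest.approx(v_brute, rel=1e-9)

    def test_mask_invariant_under_affine_rescale(self):
        rng = np.random.default_rng(7)
        img = np.concatenate([rng.normal(0, 0.2, 900), rng.normal(2, 0.3, 100)])
        img = img.reshape(25, 40)
        np.testing.assert_array_equal(otsu_segment(img), otsu_segment(3.0 * img + 5.0))

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.ones((8, 8)))


class TestLabelAndFilter:
    PITCH = 0.4364e-6

    def test_two_disjoint_disks(self):
        m = np.zeros((200, 200), bool)
        for c in ((60, 60), (140, 140)):
            rr, cc = draw.disk(c, 25)
            m[rr, cc] = True
        segs = label_and_filter(m, self.PITCH)
        assert len(segs) == 2
        assert all(not s.flagged for s in segs)

    def test_dumbbell_flagged_clustered(self):
        """Two barely-touching disks form one low-solidity component: the
        convex hull gains the waist area, pushing solidity below 0.9."""
        m = np.zeros((220, 220), bool)
        rr, cc = draw.disk((110, 70), 30)
        m[rr, cc] = True
        rr, cc = draw.disk((110, 129), 30)  # separation just under 2 R
        m[rr, cc] = True
        segs = label_and_filter(m, self.PITCH)
        assert len(segs) == 1
        assert segs[0].solidity < 0.9
        assert segs[0].clustered

    def test_moderate_overlap_caught_by_radius_gate(self):
        """Disks overlapping at 1.5 R separation keep solidity ≈0.95, so the
        equivalent-radius gate provides the clustered flag."""
        m = np.zeros((220, 220), bool)
        rr, cc = draw.disk((110, 70), 30)
        m[rr, cc] = True
        rr, cc = draw.disk((110, 115), 30)
        m[rr, cc] = True
        segs = label_and_filter(m, self.PITCH, max_radius=32 * self.PITCH)
        assert len(segs) == 1
        assert segs[0].solidity > 0.9
        assert segs[0].clustered

    def test_oversize_segment_flagged(self):
        m = np.zeros((100, 100), bool)
        rr, cc = draw.disk((50, 50), 30)
        m[rr, cc] = True
        segs = label_and_filter(m, self.PITCH, max_radius=20 * self.PITCH)
        assert segs[0].clustered

    def test_edge_clipped_disk_flagged_border(self):
        m = np.zeros((100, 100), bool)
        rr, cc = draw.disk((5, 50), 20, shape=m.shape)
        m[rr, cc] = True
        segs = label_and_filter(m, self.PITCH)
        assert segs[0].border

    def test_noise_speckle_dropped(self):
        m = np.zeros((50, 50), bool)
        m[10, 10] = True
        assert label_and_filter(m, self.PITCH, min_area_px=5) == []


class TestCellFeatures:
    def make_disk_segment(self, n, r_px):
        m = np.zeros((n, n), bool)
        rr, cc = draw.disk((n // 2, n // 2), r_px)
        m[rr, cc] = True
        return m

    def test_formulas_on_uniform_disk(self, cfg512):
        """Feature formulas against independent arithmetic."""
        mat = CELLS_IN_DMEM
        mask = self.make_disk_segment(256, 20)
        phase = np.where(mask, 3.795, 0.0)
        rec = cell_features(mask, phase, cfg512, mat)
        S = mask.sum() * cfg512.object_pitch**2
        assert rec.area == pytest.approx(S)
        assert rec.radius == pytest.approx(math.sqrt(S / math.pi), rel=1e-12)
        dm_expected = 10 * cfg512.wavelength * 3.795 * S / (2 * math.pi * 0.002)
        assert rec.dry_mass == pytest.approx(dm_expected, rel=1e-12)
        h_bar = 4 * rec.radius / 3
        assert rec.mean_thickness == pytest.approx(h_bar, rel=1e-12)
        n_expected = 1.339 + 3.795 * cfg512.wavelength / (2 * math.pi * h_bar)
        assert rec.integral_ri == pytest.approx(n_expected, rel=1e-12)

    def test_reference_cell_magnitudes(self, cfg512):
        """A mean-sized suspended tumour cell: Δφ̄ 3.795 rad over a disk of
        area ≈234.5 µm² weighs ≈365 pg by the dry-mass relation."""
        mat = CELLS_IN_DMEM
        R = 8.64e-6
        dphi = 2 * math.pi * 0.027 * (4 * R / 3) / 515e-9
        assert dphi == pytest.approx(3.795, abs=2e-3)
        S = math.pi * R**2
        assert S == pytest.approx(234.5e-12, rel=1e-3)
        dm = 10 * 515e-9 * dphi * S / (2 * math.pi * mat.beta)
        assert dm * 1e15 == pytest.approx(365.0, abs=1.0)

    def test_zero_phase_gives_medium_ri_and_no_mass(self, cfg512):
        mask = self.make_disk_segment(128, 15)
        rec = cell_features(mask, np.zeros((128, 128)), cfg512, CELLS_IN_DMEM)
        assert rec.dry_mass == 0.0
        assert rec.integral_ri == pytest.approx(1.339)

    def test_empty_segment_rejected(self, cfg512):
        with pytest.raises(ValueError):
            cell_features(np.zeros((32, 32), bool), np.zeros((32, 32)),
                          cfg512, CELLS_IN_DMEM)

    def test_dry_mass_additive_over_disjoint_segments(self, cfg512):
        mat = CELLS_IN_DMEM
        m1 = np.zeros((256, 256), bool)
        rr, cc = draw.disk((80, 80), 18)
        m1[rr, cc] = True
        m2 = np.zeros((256, 256), bool)
        rr, cc = draw.disk((170, 170), 24)
        m2[rr, cc] = True
        rng = np.random.default_rng(8)
        phase = np.abs(rng.normal(2.0, 0.5, (256, 256)))
        dm1 = cell_features(m1, phase, cfg512, mat).dry_mass
        dm2 = cell_features(m2, phase, cfg512, mat).dry_mass
        dm_union = cell_features(m1 | m2, phase, cfg512, mat).dry_mass
        assert dm_union == pytest.approx(dm1 + dm2, rel=1e-12)

    def test_features_invariant_to_offset_after_background_removal(self, cfg512):
        from holoqpi.reconstruct import QPIImage, remove_background_phase

        mask = self.make_disk_segment(256, 20)
        phase = np.where(mask, 2.5, 0.0)
        bg = ~mask

        def features_of(ph):
            q = QPIImage(phase=ph, pitch=cfg512.object_pitch,
                         wavelength=cfg512.wavelength)
            corr = remove_background_phase(q, bg)
            return cell_features(mask, corr.phase, cfg512, CELLS_IN_DMEM)

        a = features_of(phase)
        b = features_of(phase + 0.7)
        assert a.mean_phase == pytest.approx(b.mean_phase, abs=1e-10)
        assert a.dry_mass == pytest.approx(b.dry_mass, rel=1e-10)


class TestSphericalCapFit:
    def test_recovers_cap_parameters(self):
        n = 256
        c = np.arange(n) - n // 2
        X, Y = np.meshgrid(c, c, indexing="xy")
        R, amp = 21.5, 4.1
        cap = amp * np.sqrt(np.clip(1 - ((X - 3.2) ** 2 + (Y + 5.1) ** 2) / R**2,
                                    0, None))
        rng = np.random.default_rng(9)
        noisy = cap + rng.normal(0, 0.03, cap.shape)
        seed_mask = cap > 0.4 * amp
        cx, cy, R_fit, amp_fit, rms = fit_spherical_cap(noisy, seed_mask)
        assert R_fit == pytest.approx(R, rel=0.01)
        assert amp_fit == pytest.approx(amp, rel=0.02)
        assert cx == pytest.approx(n // 2 + 3.2, abs=0.3)
        assert cy == pytest.approx(n // 2 - 5.1, abs=0.3)

    def test_refinement_restores_clipped_rim(self, cfg512):
        """An Otsu-style cut at ~0.37×peak loses ~7% of the radius; the cap
        fit recovers the full projected disk."""
        n = 256
        c = np.arange(n) - n // 2
        X, Y = np.meshgrid(c, c, indexing="xy")
        R = 20.0
        cap = 5.0 * np.sqrt(np.clip(1 - (X**2 + Y**2) / R**2, 0, None))
        seed = label_and_filter(cap > 0.37 * 5.0, cfg512.object_pitch)[0]
        r_seed = math.sqrt(seed.area_px / math.pi)
        refined = refine_cell_mask(cap, seed)
        r_ref = math.sqrt(refined.area_px / math.pi)
        assert r_seed < 0.95 * R
        assert r_ref == pytest.approx(R, rel=0.02)


class TestMip:
    def test_single_frame_identity(self):
        a = np.random.default_rng(1).random((16, 16))
        np.testing.assert_array_equal(mip([a]), a)

    def test_disjoint_cells_both_present(self):
        a = np.zeros((32, 32))
        b = np.zeros((32, 32))
        a[5, 5] = 2.0
        b[20, 20] = 3.0
        out = mip([a, b])
        assert out[5, 5] == 2.0 and out[20, 20] == 3.0

    def test_dominates_every_frame(self):
        rng = np.random.default_rng(2)
        stack = rng.random((5, 16, 16))
        out = mip(stack)
        assert (out >= stack).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mip([np.zeros((4, 4)), np.zeros((5, 5))])

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            mip([])


class TestFlowPipeline:
    def test_two_cells_two_records(self, cfg256):
        """Two well-separated cells crossing the lane give two linked records."""
        spec = FlowSpec(n_frames=22, velocity=10.0, arrival_rate=0.0, seed=1)
        from holoqpi.simulate import FlowCell
        cells = [
            FlowCell(0, 6.5e-6, 1.366, 0, -45e-6, -1e-6),
            FlowCell(1, 7.5e-6, 1.364, 0, -5e-6, 2e-6),
        ]
        holos = []
        for t in range(spec.n_frames):
            obj, _ = flow_scene(spec, cfg256, t, cells=cells)
            holos.append(h.record_hologram(obj, cfg256, frame_index=t))
        blank = h.blank_hologram(cfg256)
        table, mip_phase, summary = flow_pipeline(holos, blank, cfg256,
                                                  CELLS_IN_DMEM)
        assert summary["n_cells"] == 2
        radii = sorted(table["radius_um"])
        assert radii[0] == pytest.approx(6.5, rel=0.05)
        assert radii[1] == pytest.approx(7.5, rel=0.05)

    def test_empty_stack_no_cells(self, cfg256):
        spec = FlowSpec(n_frames=3, arrival_rate=0.0, seed=0)
        holos = []
        for t in range(3):
            obj, _ = flow_scene(spec, cfg256, t, cells=[])
            holos.append(h.record_hologram(obj, cfg256, frame_index=t,
                                           photons=1e4, seed=t))
        blank = h.blank_hologram(cfg256, photons=1e4, seed=99)
        table, _, summary = flow_pipeline(holos, blank, cfg256, CELLS_IN_DMEM)
        assert summary["n_cells"] == 0
        assert len(table) == 0

    def test_geometry_mismatch_rejected(self, cfg256, cfg512):
        blank256 = h.blank_hologram(cfg256)
        blank512 = h.blank_hologram(cfg512)
        with pytest.raises(ValueError):
            flow_pipeline([blank512], blank256, cfg256, CELLS_IN_DMEM)


class TestThreeBarContrast:
    def test_ideal_target_full_contrast(self, cfg512):
        obj, bars = h.usaf_bars(cfg512, period=6e-6)
        c = three_bar_contrast(np.abs(obj.values), cfg512, 6e-6)
        assert c == pytest.approx(1.0, abs=1e-6)

    def test_flat_field_zero_contrast(self, cfg512):
        c = three_bar_contrast(np.ones((512, 512)), cfg512, 6e-6)
        assert abs(c) < 1e-9
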