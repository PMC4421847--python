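"""Beam-center determination: model fit, symmetry score, gap filling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from xdip import (
    BeamCenter,
    CuboidModel,
    DiskAssemblyModel,
    RoiSpec,
    calibrate_dual_center,
    csym,
    fit_fraunhofer,
    predict_dual_center,
    render_cuboid,
    render_disks,
    search_center,
    symmetrize_fill,
)
from xdip.center import DualCenterCalibration, auto_init
from xdip.preprocess import Frame, STATUS_MISSING, STATUS_FILLED

TRUTH_DUAL = dict(K=922.22, A=125.16, B=130.76, theta=14.92, xc=253.77, yc=256.79)


def _disk_frame(det, beam, center, positions=((0.0, 0.0), (150.0, 80.0))):
    return render_disks(DiskAssemblyModel(140.0, np.array(positions)), det, beam, center)


class TestFitFraunhofer:
    def test_noise_free_self_consistency(self, beam, dual512):
        c = BeamCenter(TRUTH_DUAL["xc"], TRUTH_DUAL["yc"], "dual")
        fr = render_cuboid(
            CuboidModel(TRUTH_DUAL["A"], TRUTH_DUAL["B"], TRUTH_DUAL["theta"],
                        TRUTH_DUAL["K"]),
            dual512, beam, c)
        res = fit_fraunhofer(fr, dual512, beam, init=TRUTH_DUAL)
        assert res.converged
        assert res.residual < 1e-12 * TRUTH_DUAL["K"] ** 2
        for p, v in TRUTH_DUAL.items():
            assert getattr(res, p) == pytest.approx(v, rel=1e-6)

    def test_noise_free_converges_from_perturbed_inits(self, beam, dual512, rng):
        c = BeamCenter(TRUTH_DUAL["xc"], TRUTH_DUAL["yc"], "dual")
        fr = render_cuboid(
            CuboidModel(TRUTH_DUAL["A"], TRUTH_DUAL["B"], TRUTH_DUAL["theta"],
                        TRUTH_DUAL["K"]),
            dual512, beam, c)
        for _ in range(3):
            init = {k: v * (1 + rng.uniform(-0.2, 0.2)) for k, v in TRUTH_DUAL.items()}
            init["xc"] = TRUTH_DUAL["xc"] + rng.uniform(-3, 3)
            init["yc"] = TRUTH_DUAL["yc"] + rng.uniform(-3, 3)
            res = fit_fraunhofer(fr, dual512, beam, init=init, weighting="none")
            assert res.residual < 1e-6 * TRUTH_DUAL["K"] ** 2

    def test_poisson_noise_recovery_within_3_sigma(self, beam, dual512, rng):
        c = BeamCenter(TRUTH_DUAL["xc"], TRUTH_DUAL["yc"], "dual")
        fr0 = render_cuboid(
            CuboidModel(TRUTH_DUAL["A"], TRUTH_DUAL["B"], TRUTH_DUAL["theta"],
                        TRUTH_DUAL["K"]),
            dual512, beam, c)
        fr = fr0.copy()
        fr.intensity = rng.poisson(fr0.intensity).astype(float)
        init = {k: v * (1 + rng.uniform(-0.1, 0.1)) for k, v in TRUTH_DUAL.items()}
        res = fit_fraunhofer(fr, dual512, beam, init=init)
        assert res.converged
        for p, v in TRUTH_DUAL.items():
            assert abs(getattr(res, p) - v) < 3 * res.sigmas[p]

    def test_fixed_edge_lengths_refine_remaining(self, beam, octal256):
        # the wide-angle stage fixes A, B from the small-angle fit
        c = BeamCenter(130.0, 126.0, "octal")
        fr = render_cuboid(CuboidModel(125.16, 130.76, 15.29, 500.0), octal256, beam, c)
        init = dict(K=400.0, A=125.16, B=130.76, theta=13.0, xc=128.5, yc=127.5)
        res = fit_fraunhofer(fr, octal256, beam, init=init,
                             fixed={"A": 125.16, "B": 130.76})
        assert res.A == 125.16 and res.B == 130.76
        assert "A" not in res.sigmas
        assert res.theta == pytest.approx(15.29, abs=1e-3)
        assert res.xc == pytest.approx(130.0, abs=1e-3)

    def test_detector_rotation_recovered_as_theta_difference(self, beam, octal256, dual512):
        # the same particle seen by both detectors, rotated by 0.37 deg
        theta_o, theta_d = 15.29, 14.92
        c_o = BeamCenter(128.0, 128.0, "octal")
        c_d = BeamCenter(TRUTH_DUAL["xc"], TRUTH_DUAL["yc"], "dual")
        fr_o = render_cuboid(CuboidModel(125.16, 130.76, theta_o, 13825.0),
                             octal256, beam, c_o)
        fr_d = render_cuboid(CuboidModel(125.16, 130.76, theta_d, 922.22),
                             dual512, beam, c_d)
        res_d = fit_fraunhofer(fr_d, dual512, beam,
                               init=dict(K=800, A=120, B=135, theta=14.0,
                                         xc=254.5, yc=256.0))
        res_o = fit_fraunhofer(fr_o, octal256, beam,
                               init=dict(K=12000, A=res_d.A, B=res_d.B, theta=15.8,
                                         xc=128.4, yc=127.6),
                               fixed={"A": res_d.A, "B": res_d.B})
        assert res_o.theta - res_d.theta == pytest.approx(0.37, abs=1e-3)

    def test_too_few_valid_pixels_rejected(self, beam, octal256):
        fr = Frame(np.zeros(octal256.shape),
                   np.full(octal256.shape, STATUS_MISSING, np.uint8))
        with pytest.raises(ValueError):
            fit_fraunhofer(fr, octal256, beam, init=TRUTH_DUAL)

    def test_auto_init_lands_near_center(self, beam, octal256):
        c = BeamCenter(132.0, 124.0, "octal")
        fr = render_cuboid(CuboidModel(125.0, 125.0, 0.0, 1000.0), octal256, beam, c)
        init = auto_init(fr)
        assert abs(init["xc"] - 132.0) < 3 and abs(init["yc"] - 124.0) < 3


class TestCsym:
    def test_exactly_one_at_true_center(self, beam, octal256):
        c = BeamCenter(127.0, 127.0, "octal")
        fr = _disk_frame(octal256, beam, c)
        assert csym(fr, (127, 127)) == pytest.approx(1.0, abs=1e-12)

    def test_below_one_off_center(self, beam, octal256):
        c = BeamCenter(127.0, 127.0, "octal")
        fr = _disk_frame(octal256, beam, c)
        assert csym(fr, (128, 127)) < 1.0
        assert csym(fr, (127, 128)) < 1.0

    def test_matches_brute_force_pairwise(self, rng):
        # independent oracle: explicit double loop over ROI pixels
        spec = RoiSpec(radius=8.0, size=6, angles=(0.0, 90.0))
        for _ in range(5):
            inten = rng.uniform(0, 10, (32, 32))
            status = (rng.random((32, 32)) < 0.15).astype(np.uint8)
            fr = Frame(inten, status)
            cx, cy = int(rng.integers(14, 18)), int(rng.integers(14, 18))
            num = den = 0.0
            for dx0, dy0 in spec.offsets():
                for dy in range(spec.size):
                    for dx in range(spec.size):
                        x, y = cx + dx0 + dx, cy + dy0 + dy
                        mx, my = 2 * cx - x, 2 * cy - y
                        if status[y, x] == 0 and status[my, mx] == 0:
                            i1, i2 = inten[y, x], inten[my, mx]
                            num += abs(i1 - i2)
                            den += i1 + i2
            expected = 1.0 - num / den
            assert csym(fr, (cx, cy), spec, min_pairs=1) == pytest.approx(expected, rel=1e-12)

    @given(st.integers(0, 2**32 - 1))
    def test_bounded_by_one(self, seed):
        rng = np.random.default_rng(seed)
        fr = Frame(rng.uniform(0, 100, (64, 64)), np.zeros((64, 64), np.uint8))
        spec = RoiSpec(radius=12.0, size=8)
        s = csym(fr, (32, 32), spec, min_pairs=1)
        assert 0.0 <= s <= 1.0

    def test_too_few_pairs_rejected(self):
        fr = Frame(np.ones((64, 64)), np.full((64, 64), STATUS_MISSING, np.uint8))
        with pytest.raises(ValueError):
            csym(fr, (32, 32), RoiSpec(radius=12.0, size=8))


class TestSearchCenter:
    def test_window_one_returns_prior(self, beam, octal256):
        prior = BeamCenter(127.0, 127.0, "octal")
        fr = _disk_frame(octal256, beam, prior)
        cmap = search_center(fr, 1, prior)
        assert (cmap.best.x, cmap.best.y) == (127.0, 127.0)

    def test_recovers_shifted_center(self, beam, octal256):
        true = BeamCenter(131.0, 124.0, "octal")
        fr = _disk_frame(octal256, beam, true)
        cmap = search_center(fr, 21, BeamCenter(127.0, 127.0, "octal"))
        assert (cmap.best.x, cmap.best.y) == (131.0, 124.0)
        assert np.nanmax(cmap.scores) == pytest.approx(1.0, abs=1e-12)

    def test_even_window_rejected(self, beam, octal256):
        fr = _disk_frame(octal256, beam, BeamCenter(127.0, 127.0, "octal"))
        with pytest.raises(ValueError):
            search_center(fr, 4, BeamCenter(127.0, 127.0, "octal"))

    def test_tie_breaks_toward_prior(self):
        # a constant frame scores 1 everywhere: the prior must win
        fr = Frame(np.full((128, 128), 3.0), np.zeros((128, 128), np.uint8))
        prior = BeamCenter(64.0, 64.0, "octal")
        cmap = search_center(fr, 5, prior, RoiSpec(radius=12.0, size=8))
        assert (cmap.best.x, cmap.best.y) == (64.0, 64.0)

    def test_subpixel_refinement_stays_within_half_pixel(self, beam, octal256):
        true = BeamCenter(128.4, 126.7, "octal")
        fr = _disk_frame(octal256, beam, true)
        cmap = search_center(fr, 7, BeamCenter(127.0, 127.0, "octal"))
        refined = cmap.refine_subpixel()
        assert abs(refined.x - cmap.best.x) <= 0.5
        assert abs(refined.y - cmap.best.y) <= 0.5
        # refinement moves toward the fractional truth
        assert abs(refined.x - true.x) <= abs(cmap.best.x - true.x) + 1e-9


class TestSymmetrizeFill:
    def test_no_missing_pixels_unchanged(self, beam, octal256):
        c = BeamCenter(127.0, 127.0, "octal")
        fr = _disk_frame(octal256, beam, c)
        out = symmetrize_fill(fr, c)
        assert np.array_equal(out.intensity, fr.intensity)
        assert np.array_equal(out.status, fr.status)

    def test_masked_stripe_restored_exactly(self, beam, octal256):
        c = BeamCenter(127.0, 127.0, "octal")
        fr = _disk_frame(octal256, beam, c)
        truth = fr.intensity.copy()
        fr.status[:, 40:44] = STATUS_MISSING
        fr.intensity[:, 40:44] = 0.0
        out = symmetrize_fill(fr, c)
        # row 255 has no mate inside the frame (reflection of y about 127
        # is 254 - y); everything else is restored exactly
        filled = out.status[:255, 40:44] == STATUS_FILLED
        assert filled.all()
        assert np.allclose(out.intensity[:255, 40:44], truth[:255, 40:44], rtol=1e-10)
        assert np.all(out.status[255, 40:44] == STATUS_MISSING)

    def test_symmetric_pair_both_missing_stays_missing(self, beam, octal256):
        c = BeamCenter(127.0, 127.0, "octal")
        fr = _disk_frame(octal256, beam, c)
        fr.status[127, 100] = STATUS_MISSING
        fr.status[127, 154] = STATUS_MISSING  # the Friedel mate
        out = symmetrize_fill(fr, c)
        assert out.status[127, 100] == STATUS_MISSING
        assert out.status[127, 154] == STATUS_MISSING


class TestPredictDualCenter:
    def test_identity_geometry(self):
        calib = DualCenterCalibration(slope=1.0, offset_x=0.0, offset_y=0.0)
        c = BeamCenter(100.0, 110.0, "octal")
        out = predict_dual_center(c, calib)
        assert (out.x, out.y) == (100.0, 110.0)

    def test_slope_is_camera_length_ratio(self):
        pairs = [
            (BeamCenter(100.0, 100.0, "octal"), BeamCenter(210.0, 195.0, "dual")),
            (BeamCenter(104.0, 98.0, "octal"), BeamCenter(218.0, 191.0, "dual")),
        ]
        calib = calibrate_dual_center(pairs, 1.6, 3.2)
        assert calib.slope == 2.0

    def test_calibrate_and_predict_held_out_pair(self, rng):
        slope, ox, oy = 2.0, 10.0, -6.0
        pairs = []
        for _ in range(5):
            o = BeamCenter(float(rng.uniform(90, 160)), float(rng.uniform(90, 160)), "octal")
            d = BeamCenter(slope * o.x + ox + rng.normal(0, 0.2),
                           slope * o.y + oy + rng.normal(0, 0.2), "dual")
            pairs.append((o, d))
        calib = calibrate_dual_center(pairs[:4], 1.6, 3.2)
        o, d = pairs[4]
        pred = predict_dual_center(o, calib)
        assert abs(pred.x - d.x) < 1.0 and abs(pred.y - d.y) < 1.0

    def test_requires_two_pairs(self):
        with pytest.raises(ValueError):
            calibrate_dual_center([(BeamCenter(0, 0), BeamCenter(0, 0))], 1.6, 3.2)
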