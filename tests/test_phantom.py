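"""Phantom generator: determinism, construction guarantees, recovery oracles."""

import numpy as np
import pytest

from cemct.calibration import fit_calibration
from cemct.image import SubtractionConfig, Volume, subtract
from cemct.kinetics import PatlakWindow, extract_curve, patlak_fit, patlak_transform
from cemct.phantom import (HistologySimSpec, KineticGroundTruth, Organ,
                           PhantomSpec, default_rat_spec,
                           make_calibration_phantom, make_dce_series,
                           make_de_pair, make_histology_table, make_se_pair,
                           projected_roi, projection_thickness)
from cemct.registration import AffineTransform
from cemct.voi import EllipsoidVOI, sample_voi


def _zero_iodine_spec(seed=0, sigma=0.0):
    spec = default_rat_spec(seed=seed, noise_sigma_hu=sigma)
    for o in spec.organs:
        o.iodine_mg_ml = 0.0
    return spec


class TestPhantomSpec:
    def test_organ_outside_bounds_rejected(self):
        organ = Organ(EllipsoidVOI((2.0, 24.0, 24.0), (8.0, 4.0, 4.0), "liver"), 40.0)
        with pytest.raises(ValueError, match="liver"):
            PhantomSpec((49, 49, 49), (1.0, 1.0, 1.0), [organ])

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            PhantomSpec((9, 9, 9), (1, 1, 1), [], noise_sigma_hu=-1.0)

    def test_negative_iodine_rejected(self):
        with pytest.raises(ValueError, match="iodine"):
            Organ(EllipsoidVOI((4, 4, 4), (1, 1, 1), "tumor"), 40.0, iodine_mg_ml=-0.5)


class TestSePair:
    def test_zero_iodine_identity(self):
        baseline, ce = make_se_pair(_zero_iodine_spec())
        assert np.array_equal(baseline.data, ce.data)

    def test_tumor_enhancement_arithmetic_oracle(self, rat_spec):
        """mean(CE - baseline) over the tumor = C_I / slope = 1.55 / 0.02."""
        baseline, ce = make_se_pair(rat_spec, cal_slope=0.02)
        tumor = rat_spec.organ("tumor").voi
        diff = Volume(ce.data - baseline.data, rat_spec.spacing, "enhancement_hu")
        assert sample_voi(diff, tumor).mean == pytest.approx(1.55 / 0.02, rel=1e-12)

    def test_determinism(self):
        spec = default_rat_spec(seed=123, noise_sigma_hu=5.0)
        b1, c1 = make_se_pair(spec)
        b2, c2 = make_se_pair(spec)
        assert np.array_equal(b1.data, b2.data)
        assert np.array_equal(c1.data, c2.data)

    def test_different_seed_differs(self):
        b1, _ = make_se_pair(default_rat_spec(seed=1, noise_sigma_hu=5.0))
        b2, _ = make_se_pair(default_rat_spec(seed=2, noise_sigma_hu=5.0))
        assert not np.array_equal(b1.data, b2.data)

    def test_noise_independent_between_members(self):
        baseline, ce = make_se_pair(_zero_iodine_spec(seed=3, sigma=5.0))
        assert not np.array_equal(baseline.data, ce.data)

    def test_misalignment_moves_baseline_only(self):
        spec = default_rat_spec()
        spec.misalignment = AffineTransform(np.eye(3), np.array([2.0, 0.0, 0.0]))
        b_mis, ce_mis = make_se_pair(spec)
        b_ref, ce_ref = make_se_pair(default_rat_spec())
        assert np.array_equal(ce_mis.data, ce_ref.data)
        assert not np.array_equal(b_mis.data, b_ref.data)


class TestDePair:
    def test_zero_iodine_exact_cancellation(self):
        le, he = make_de_pair(_zero_iodine_spec())
        assert np.abs(he.data - 0.55 * le.data).max() == 0.0

    def test_iodine_signal_only_inside_organs(self, rat_spec):
        le, he = make_de_pair(rat_spec)
        de = he.data - 0.55 * le.data
        iodinated = np.zeros(rat_spec.shape, bool)
        for o in rat_spec.organs:
            if o.iodine_mg_ml > 0:
                iodinated |= o.voi.mask(rat_spec.shape, rat_spec.spacing)
        assert np.all(de[iodinated] > 0)
        assert np.abs(de[~iodinated]).max() == 0.0

    def test_noisy_residual_zero_within_3_sem(self):
        """Monte-Carlo: weighted residual averages to 0 over tissue (seeded)."""
        spec = _zero_iodine_spec(seed=77, sigma=4.0)
        le, he = make_de_pair(spec)
        voi = EllipsoidVOI((24.0, 24.0, 24.0), (14.0, 14.0, 14.0), "custom")
        m = voi.mask(spec.shape, spec.spacing)
        resid = (he.data - 0.55 * le.data)[m]
        sem = resid.std(ddof=1) / np.sqrt(resid.size)
        assert abs(resid.mean()) < 3 * sem

    def test_weighted_subtraction_pipeline(self, rat_spec):
        le, he = make_de_pair(rat_spec)
        le.frame = he.frame = "de"
        e = subtract(he, le, SubtractionConfig("weighted_de", 0.55))
        tumor = rat_spec.organ("tumor").voi
        assert sample_voi(e, tumor).mean == pytest.approx(1.55 / 0.02, rel=1e-12)


class TestDceSeries:
    def test_unknown_truth_region_named(self, rat_spec):
        truth = KineticGroundTruth(regions={"spleen": (0.1, 0.1)})
        with pytest.raises(KeyError, match="spleen"):
            make_dce_series(rat_spec, truth)

    def test_projection_conservation(self, rat_spec, kinetic_truth):
        """Frame sum equals the voxel-size-weighted sum of the 3-D map."""
        series = make_dce_series(rat_spec, kinetic_truth, axis=0)
        k = 50  # arbitrary frame
        cmap = np.zeros(rat_spec.shape)
        for o in rat_spec.organs:
            label = o.voi.label
            m = o.voi.mask(rat_spec.shape, rat_spec.spacing)
            if label in kinetic_truth.regions:
                cmap[m] = kinetic_truth.tissue_curve(label).ci_mg_ml[k]
            else:
                cmap[m] = o.iodine_mg_ml
        assert series.frames[k].sum() == pytest.approx(
            cmap.sum() * rat_spec.spacing[0], rel=1e-12)

    def test_extracted_curve_matches_forward_via_thickness(self, rat_spec, kinetic_truth):
        """Projection scale factor fully accounted for by mean chord thickness."""
        series = make_dce_series(rat_spec, kinetic_truth, axis=0)
        roi = projected_roi(rat_spec, "tumor", axis=0)
        th = projection_thickness(rat_spec, "tumor", axis=0)
        curve = extract_curve(series, roi, "tumor", thickness_mm=th)
        gen = kinetic_truth.tissue_curve("tumor")
        nz = gen.ci_mg_ml > 0
        rel = np.abs(curve.ci_mg_ml[nz] - gen.ci_mg_ml[nz]) / gen.ci_mg_ml[nz]
        assert rel.max() < 5e-3

    def test_overlap_organ_biases_upward(self, rat_spec, kinetic_truth):
        """Planar superimposition: overlapping organ inflates the tumor curve."""
        tumor_voi = rat_spec.organ("tumor").voi
        overlap = Organ(EllipsoidVOI((40.0, tumor_voi.center[1], tumor_voi.center[2]),
                                     (5.0, 4.0, 4.0), "custom"),
                        baseline_hu=40.0, iodine_mg_ml=2.0)
        clean = make_dce_series(rat_spec, kinetic_truth, axis=0)
        dirty = make_dce_series(rat_spec, kinetic_truth, axis=0, overlap=overlap)
        roi = projected_roi(rat_spec, "tumor", axis=0)
        c_clean = extract_curve(clean, roi, "tumor")
        c_dirty = extract_curve(dirty, roi, "tumor")
        assert np.all(c_dirty.ci_mg_ml > c_clean.ci_mg_ml)

    def test_forward_inverse_through_series(self, rat_spec, kinetic_truth):
        """Patlak fit on the noise-free series recovers the generating values.

        Thickness normalization cancels in neither x nor y unless applied to
        both curves; with per-region thickness both parameters are exact.
        """
        # the aorta acts as the blood pool: rBV fraction 1 makes it carry the AIF
        truth = KineticGroundTruth(regions={"tumor": (0.24, 0.116),
                                            "aorta": (0.0, 1.0)})
        series = make_dce_series(rat_spec, truth, axis=0)
        w = PatlakWindow()
        aif = extract_curve(series, projected_roi(rat_spec, "aorta"), "lv",
                            thickness_mm=projection_thickness(rat_spec, "aorta"))
        tumor = extract_curve(series, projected_roi(rat_spec, "tumor"), "tumor",
                              thickness_mm=projection_thickness(rat_spec, "tumor"))
        fit = patlak_fit(patlak_transform(tumor, aif, w), w)
        assert fit.ktrans_per_min == pytest.approx(0.24, rel=1e-2)
        assert fit.rbv_percent == pytest.approx(11.6, rel=1e-2)

    def test_determinism(self, rat_spec, kinetic_truth):
        s1 = make_dce_series(rat_spec, kinetic_truth, noise_sigma=1.0)
        s2 = make_dce_series(rat_spec, kinetic_truth, noise_sigma=1.0)
        assert np.array_equal(s1.frames, s2.frames)


class TestCalibrationPhantom:
    def test_construction_enhancements(self):
        vol, vois = make_calibration_phantom([0.0, 1.0, 2.0], hu_per_mg_ml=50.0)
        means = [sample_voi(vol, v).mean for v in vois]
        assert means == pytest.approx([0.0, 50.0, 100.0], abs=1e-12)

    def test_zero_concentration_insert_zero(self):
        vol, vois = make_calibration_phantom([0.0, 1.0, 2.0])
        assert sample_voi(vol, vois[0]).mean == 0.0

    def test_noisy_refit_slope_within_2pct(self):
        """Least-squares recovery of the generating slope at fixed seed."""
        conc = [0.0, 0.5, 1.0, 2.0, 4.0]
        vol, vois = make_calibration_phantom(conc, hu_per_mg_ml=50.0,
                                             noise_sigma_hu=2.0, seed=11)
        points = [(sample_voi(vol, v).mean, c) for v, c in zip(vois, conc)]
        cal = fit_calibration(points, "SE")
        assert cal.slope == pytest.approx(1 / 50.0, rel=0.02)

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError, match="3 distinct"):
            make_calibration_phantom([0.0, 1.0])

    def test_negative_concentration(self):
        with pytest.raises(ValueError, match=">= 0"):
            make_calibration_phantom([-1.0, 0.0, 1.0])


class TestHistology:
    def test_perfect_correlation(self):
        sim = HistologySimSpec(n_tumors=20, seed=0,
                               rho={"mvd_vessels_per_hpf": 1.0})
        values = np.linspace(10, 30, 20)
        df = make_histology_table(sim, values)
        r = np.corrcoef(values, df["mvd_vessels_per_hpf"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_null_correlation_large_n(self):
        sim = HistologySimSpec(n_tumors=10_000, seed=5)
        values = np.random.default_rng(99).normal(25, 5, 10_000)
        df = make_histology_table(sim, values)
        for col in ("pn_percent", "pi_percent", "mvd_vessels_per_hpf"):
            assert abs(np.corrcoef(values, df[col])[0, 1]) < 0.03

    def test_percent_clipping(self):
        sim = HistologySimSpec(n_tumors=1000, seed=1,
                               means={"pn_percent": 95.0, "pi_percent": 5.0,
                                      "mvd_vessels_per_hpf": 1.0},
                               sds={"pn_percent": 20.0, "pi_percent": 20.0,
                                    "mvd_vessels_per_hpf": 2.0})
        df = make_histology_table(sim, np.random.default_rng(2).normal(0, 1, 1000))
        assert df["pn_percent"].between(0, 100).all()
        assert df["pi_percent"].between(0, 100).all()
        assert (df["mvd_vessels_per_hpf"] >= 0).all()

    def test_marginals_recovered(self):
        sim = HistologySimSpec(n_tumors=5000, seed=3)
        values = np.random.default_rng(31).normal(25, 5, 5000)
        df = make_histology_table(sim, values)
        assert df["pi_percent"].mean() == pytest.approx(68.7, abs=1.0)

    def test_small_n_rejected(self):
        sim = HistologySimSpec(n_tumors=2)
        with pytest.raises(ValueError, match="3 tumors"):
            make_histology_table(sim, [1.0, 2.0])

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            HistologySimSpec(n_tumors=5, rho={"pn_percent": 1.5})

    def test_determinism(self):
        sim = HistologySimSpec(n_tumors=10, seed=9)
        v = np.arange(10.0)
        assert make_histology_table(sim, v).equals(make_histology_table(sim, v))
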