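"""Phantom generator: boundary geometry, closed-form AUC oracle, rendering,
and cohort synthesis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from fovtopo.layers import BOUNDARIES, thickness_profiles
from fovtopo.phantom import (
    ClampWarning,
    FoveaPhenotype,
    GridTooShortError,
    LayerShape,
    MotionModel,
    ScanGrid,
    analytic_quadrant_auc,
    layer_thickness_um,
    make_boundary_profiles,
    make_cohort,
    phenotype_preset,
    render_base_image,
    render_bscan_stack,
)

QUADS = ("temporal", "nasal", "inferior", "superior")


def _flat_phenotype(**band):
    """Phenotype with a single interesting band and flat other bands."""
    layers = {b: LayerShape(50.0, 0.0, 0.0) for b in ("RNFL", "GCL", "IPL", "INL_OPL", "OUTER")}
    for name, shape in band.items():
        layers[name] = shape
    return FoveaPhenotype(layers=layers)


class TestGeometry:
    @pytest.mark.parametrize("preset", ["control", "grade1", "grade2", "grade3", "grade4"])
    @pytest.mark.parametrize("rho", [1.0, 1.2, 1.45])
    def test_boundary_ordering_everywhere(self, preset, rho):
        contours, _ = make_boundary_profiles(phenotype_preset(preset, rho_nt=rho))
        contours.validate()  # raises on any crossing
        for upper, lower in zip(BOUNDARIES[:-1], BOUNDARIES[1:]):
            assert np.all(contours.boundaries[lower] >= contours.boundaries[upper])

    @given(
        pit=st.floats(0.0, 40.0),
        rim=st.floats(0.0, 20.0),
        rho=st.floats(0.8, 1.6),
    )
    def test_boundary_ordering_property(self, pit, rim, rho):
        ph = _flat_phenotype(GCL=LayerShape(45.0, pit, rim))
        ph = FoveaPhenotype(layers=ph.layers, rho_nt=rho)
        contours, _ = make_boundary_profiles(ph)
        contours.validate()

    def test_control_center_value_and_symmetry(self, control_phenotype):
        shape = control_phenotype.layers["GCL"]
        x = np.linspace(-2.5, 2.5, 501)
        t = layer_thickness_um(control_phenotype, "GCL", x)
        expected_center = shape.baseline_um - shape.pit_um + shape.rim_um
        assert t[250] == pytest.approx(expected_center)
        # rho_nt = rho_si = 1: even function
        assert np.allclose(t, t[::-1])

    def test_grade4_has_no_pit(self):
        ph = phenotype_preset("grade4")
        assert all(s.pit_um == 0 for s in ph.layers.values())
        shape = ph.layers["GCL"]
        t0 = layer_thickness_um(ph, "GCL", np.array([0.0]))[0]
        t_edge = layer_thickness_um(ph, "GCL", np.array([2.5]))[0]
        # foveal thickness equals edge thickness up to the rim Gaussian term
        rim_term = shape.rim_um * (1.0 - np.exp(-2.5**2 / (2 * ph.sigma_rim_mm**2)))
        assert t0 - t_edge == pytest.approx(rim_term, abs=1e-9)
        assert t0 > 40.0  # inner layers retained across the fovea

    def test_gcl_plus_ipl_equals_gcipl(self, control_scan):
        contours, truth = control_scan
        profs = thickness_profiles(contours)
        assert np.allclose(
            profs["GCL"].thickness_um + profs["IPL"].thickness_um,
            profs["GCIPL"].thickness_um,
            atol=1e-9,
        )
        assert np.allclose(
            truth["GCL"].thickness_um + truth["IPL"].thickness_um,
            truth["GCIPL"].thickness_um,
            atol=1e-12,
        )

    def test_grid_too_short(self, control_phenotype):
        grid = ScanGrid(n_ascans=1000, nominal_length_mm=4.0)  # ±2 mm only
        with pytest.raises(GridTooShortError):
            make_boundary_profiles(control_phenotype, grid=grid)

    def test_os_horizontal_mirrors_od(self, control_phenotype):
        ph = phenotype_preset("control", rho_nt=1.3)
        od, _ = make_boundary_profiles(ph, eye="OD")
        os_, _ = make_boundary_profiles(ph, eye="OS")
        # same anatomy, mirrored image: boundary traces are reverses
        assert np.allclose(od.boundaries["GCL_IPL"], os_.boundaries["GCL_IPL"][::-1])


class TestAnalyticAUC:
    def test_constant_layer(self):
        ph = _flat_phenotype(GCL=LayerShape(100.0, 0.0, 0.0))
        for q in QUADS:
            assert analytic_quadrant_auc(ph, "GCL", q) == pytest.approx(0.25, abs=1e-12)

    def test_derived_example_vs_quadrature(self):
        # B=100, a_p=80, sigma_p=0.3, a_r=30, sigma_r=1.0, rho=1
        ph = _flat_phenotype(GCL=LayerShape(100.0, 80.0, 30.0))
        ph = FoveaPhenotype(layers=ph.layers, sigma_pit_mm=0.3, sigma_rim_mm=1.0)
        val = analytic_quadrant_auc(ph, "GCL", "nasal")
        oracle, _ = quad(
            lambda x: 100.0 - 80.0 * np.exp(-x**2 / (2 * 0.3**2))
            + 30.0 * np.exp(-x**2 / (2 * 1.0**2)),
            0.0, 2.5, epsabs=1e-13, limit=200,
        )
        assert val == pytest.approx(oracle / 1000.0, abs=1e-9)
        # frozen value from the same adaptive quadrature
        assert val == pytest.approx(0.2570529251, abs=1e-9)

    @pytest.mark.parametrize("rho", [1.04, 1.2, 1.45])
    @pytest.mark.parametrize("quadrant", QUADS)
    def test_blended_closed_form_vs_quadrature(self, rho, quadrant):
        ph = phenotype_preset("control", rho_nt=rho, rho_si=rho)
        axis = "nt" if quadrant in ("temporal", "nasal") else "si"
        a, b = (0.0, 2.5) if quadrant in ("nasal", "superior") else (-2.5, 0.0)
        val = analytic_quadrant_auc(ph, "GCL", quadrant)
        oracle, _ = quad(
            lambda x: layer_thickness_um(ph, "GCL", np.array([x]), axis=axis)[0],
            a, b, epsabs=1e-13, limit=200,
        )
        assert val == pytest.approx(oracle / 1000.0, abs=1e-9)

    def test_sharp_blend_ratio_is_exactly_rho(self):
        ph = _flat_phenotype(GCL=LayerShape(100.0, 80.0, 30.0))
        ph = FoveaPhenotype(layers=ph.layers, rho_nt=1.2, blend_halfwidth_mm=0.0)
        nasal = analytic_quadrant_auc(ph, "GCL", "nasal")
        temporal = analytic_quadrant_auc(ph, "GCL", "temporal")
        assert nasal / temporal == pytest.approx(1.2, abs=1e-12)

    def test_composites_sum(self, control_phenotype):
        for q in QUADS:
            gcl = analytic_quadrant_auc(control_phenotype, "GCL", q)
            ipl = analytic_quadrant_auc(control_phenotype, "IPL", q)
            gcipl = analytic_quadrant_auc(control_phenotype, "GCIPL", q)
            assert gcipl == pytest.approx(gcl + ipl, abs=1e-12)

    def test_clamped_profile_falls_back_with_warning(self):
        ph = _flat_phenotype(GCL=LayerShape(10.0, 60.0, 0.0))  # goes negative
        with pytest.warns(ClampWarning):
            val = analytic_quadrant_auc(ph, "GCL", "nasal")
        oracle, _ = quad(
            lambda x: max(10.0 - 60.0 * np.exp(-x**2 / (2 * 0.3**2)), 0.0),
            0.0, 2.5, limit=200,
        )
        assert val == pytest.approx(oracle / 1000.0, abs=1e-7)

    def test_summed_auc_magnitude_matches_study_scale(self, control_phenotype):
        # control preset calibrated to the reported ~0.34 mm^2 summed GCL AUC
        total = sum(analytic_quadrant_auc(control_phenotype, "GCL", q) for q in QUADS)
        assert 0.30 < total < 0.38


class TestRender:
    def test_zero_motion_zero_noise_frames_identical(self, control_phenotype, small_grid):
        contours, _ = make_boundary_profiles(
            control_phenotype, grid=small_grid, halfwidth_mm=0.7
        )
        stack = render_bscan_stack(
            contours, MotionModel(0, 0), n_frames=5, noise_level=0.0, seed=0
        )
        for k in range(1, 5):
            assert np.array_equal(stack.frames[k], stack.frames[0])

    def test_known_shift_is_exact_translation(self, control_phenotype, small_grid):
        contours, _ = make_boundary_profiles(
            control_phenotype, grid=small_grid, halfwidth_mm=0.7
        )
        motion = MotionModel(
            lateral_shifts=[0, 3], axial_shifts=[0, 0]
        )
        stack = render_bscan_stack(contours, motion, n_frames=2, noise_level=0.0, seed=0)
        rolled = np.roll(stack.frames[0], 3, axis=1)
        # circular padding region excluded from the comparison
        assert np.array_equal(stack.frames[1][:, 3:], rolled[:, 3:])

    def test_seed_determinism(self, control_phenotype, small_grid):
        contours, _ = make_boundary_profiles(
            control_phenotype, grid=small_grid, halfwidth_mm=0.7
        )
        m = MotionModel(3, 2, strip_jitter_sd_px=1.0, drop_prob=0.1)
        s1 = render_bscan_stack(contours, m, n_frames=8, seed=42)
        s2 = render_bscan_stack(contours, m, n_frames=8, seed=42)
        assert np.array_equal(s1.frames, s2.frames)
        for key in s1.true_shifts:
            assert np.array_equal(s1.true_shifts[key], s2.true_shifts[key])

    def test_shift_beyond_bounds_raises(self, control_phenotype, small_grid):
        contours, _ = make_boundary_profiles(
            control_phenotype, grid=small_grid, halfwidth_mm=0.7
        )
        motion = MotionModel(lateral_shifts=[0, 500], axial_shifts=[0, 0])
        with pytest.raises(ValueError, match="bounds"):
            render_bscan_stack(contours, motion, n_frames=2, seed=0)

    def test_non_integer_shift_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            MotionModel(lateral_shifts=[0.5, 1.0], axial_shifts=[0, 0])

    def test_base_image_bands_have_contrast(self, control_phenotype, small_grid):
        contours, _ = make_boundary_profiles(
            control_phenotype, grid=small_grid, halfwidth_mm=0.7
        )
        img = render_base_image(contours)
        assert img.shape == (small_grid.n_rows, small_grid.n_ascans)
        assert img.std() > 0.1


class TestCohort:
    def test_counts_and_determinism(self):
        c1 = make_cohort(n_control=4, n_albinism=5, seed=7,
                         grid=ScanGrid(n_ascans=600, nominal_length_mm=7.0))
        c2 = make_cohort(n_control=4, n_albinism=5, seed=7,
                         grid=ScanGrid(n_ascans=600, nominal_length_mm=7.0))
        assert len(c1.table) == 9
        assert (c1.table["group"] == "control").sum() == 4
        assert (c1.table["group"] == "albinism").sum() == 5
        assert c1.table.equals(c2.table)
        key = next(iter(c1.scans))
        assert np.array_equal(
            c1.scans[key].contours_rep1.boundaries["GCL_IPL"],
            c2.scans[key].contours_rep1.boundaries["GCL_IPL"],
        )

    def test_rho_ranges_respected_and_separated(self):
        cohort = make_cohort(n_control=10, n_albinism=10, seed=3,
                             grid=ScanGrid(n_ascans=600, nominal_length_mm=7.0))
        ctrl = cohort.table[cohort.table["group"] == "control"]["rho_nt_true"]
        alb = cohort.table[cohort.table["group"] == "albinism"]["rho_nt_true"]
        assert ctrl.between(1.04, 1.36).all()
        assert alb.between(1.37, 1.53).all()
        assert alb.min() > ctrl.max()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(n_control=0, n_albinism=5, seed=0)

    def test_repeat_segmentations_share_truth(self):
        cohort = make_cohort(n_control=2, n_albinism=2, seed=11,
                             grid=ScanGrid(n_ascans=600, nominal_length_mm=7.0))
        rec = next(iter(cohort.scans.values()))
        d = rec.contours_rep1.boundaries["GCL_IPL"] - rec.contours_rep2.boundaries["GCL_IPL"]
        # independent noise, same underlying boundary
        assert 0 < np.abs(d).max() < 5.0

    def test_albinism_scans_carry_observer_marks(self):
        cohort = make_cohort(n_control=1, n_albinism=2, seed=2,
                             grid=ScanGrid(n_ascans=600, nominal_length_mm=7.0))
        for (pid, _, _), rec in cohort.scans.items():
            group = cohort.table.set_index("participant")["group"][pid]
            if group == "albinism":
                assert rec.observer_marks_mm is not None
                assert len(rec.observer_marks_mm) == 2
                for m in rec.observer_marks_mm:
                    assert abs(m - rec.truth_center_mm) < 0.5
            else:
                assert rec.observer_marks_mm is None
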