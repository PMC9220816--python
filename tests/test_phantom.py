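import numpy as np
import pytest

from epedetect.epe_pipeline import PipelineParams, detect_epe
from epedetect.phantom import (
    LesionSpec,
    PhantomSpec,
    make_case,
    make_cohort,
    make_prostate,
    oracle_contact_length,
    support_radius,
)

from conftest import TEST_DILATION_PX, TEST_SHAPE, TEST_SPACING, simple_spec, straddle_spec


class TestMakeProstate:
    def test_voxel_count_matches_analytic_volume(self):
        """At the default 0.29 mm resolution the ellipsoid voxel count is
        within 2% of 4/3 pi a b c / voxel volume."""
        spec = PhantomSpec(semi_axes_mm=(20.0, 16.0, 14.0))
        mask = make_prostate(spec)
        vox_vol = np.prod(spec.spacing)
        analytic = 4.0 / 3.0 * np.pi * 20.0 * 16.0 * 14.0
        assert mask.data.sum() * vox_vol == pytest.approx(analytic, rel=0.02)

    def test_degenerate_semi_axis_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            PhantomSpec(semi_axes_mm=(20.0, 0.0, 14.0))

    def test_ellipsoid_must_fit_grid(self):
        with pytest.raises(ValueError, match="bounds"):
            PhantomSpec(shape=(32, 32, 4), spacing=(0.5, 0.5, 3.0), semi_axes_mm=(20, 16, 14))


class TestSupportRadius:
    def test_zero_alpha_full_radius(self):
        assert support_radius(8.0, 0.9, 0.0) == 8.0

    def test_alpha_at_peak_empty(self):
        assert support_radius(8.0, 0.9, 0.9) == 0.0

    def test_kernel_level_set(self):
        """The cosine kernel evaluated at the support radius equals alpha."""
        r = support_radius(8.0, 0.9, 0.3)
        val = 0.9 * (1 + np.cos(np.pi * r / 8.0)) / 2
        assert val == pytest.approx(0.3)


class TestMakeCase:
    def test_interior_lesion_no_epe(self):
        case = make_case(simple_spec([LesionSpec(radius_mm=4.0, placement="interior")]))
        assert not case.gt_epe.data.any()
        assert case.gt_cancer.data.any()

    def test_epe_is_extracapsular_cancer(self, straddling_case):
        epe = straddling_case.gt_epe.astype_bool()
        cancer = straddling_case.gt_cancer.astype_bool()
        pr = straddling_case.prostate.astype_bool()
        assert epe.any()
        assert np.all(epe <= cancer)
        assert not np.any(epe & pr)

    def test_seeded_determinism(self):
        spec1 = straddle_spec(12.0, 8.0, noise=0.05, seed=9)
        spec2 = straddle_spec(12.0, 8.0, noise=0.05, seed=9)
        c1, c2 = make_case(spec1), make_case(spec2)
        assert np.array_equal(c1.p_ca.data, c2.p_ca.data)
        c3 = make_case(straddle_spec(12.0, 8.0, noise=0.05, seed=10))
        assert not np.array_equal(c1.p_ca.data, c3.p_ca.data)

    def test_target_contact_arc_is_met(self):
        for target in (6.0, 10.0, 14.0):
            case = make_case(straddle_spec(target, 8.5))
            assert case.lesions[0].contact_mm == pytest.approx(target, abs=0.1)

    def test_infeasible_contact_arc_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            make_case(straddle_spec(25.0, 6.0))

    def test_noise_stays_below_operating_threshold(self):
        """Default 0.05 noise alone cannot create candidates at alpha 0.30."""
        case = make_case(simple_spec([], noise=0.05, seed=2))
        assert case.p_ca.data.max() <= 0.05 + 1e-12

    def test_exterior_lesion_detached_and_rejected(self, test_params):
        case = make_case(
            simple_spec(
                [LesionSpec(radius_mm=4.0, placement="exterior", gap_mm=1.5, direction_deg=90)]
            )
        )
        assert not np.any(case.gt_cancer.astype_bool() & case.prostate.astype_bool())
        q, cands = detect_epe(case.p_ca, case.prostate, test_params)
        assert not q.data.any()

    def test_oracle_matches_pipeline_contact_length(self):
        """Pipeline TCL at alpha -> 0 agrees with the analytic arc oracle
        within 2 pixel lengths on the full kernel support."""
        tol_mm = 2 * TEST_SPACING[0]
        for target, radius, direction in [(13, 8.5, 90), (8, 5.5, 270), (16, 10, 45)]:
            case = make_case(straddle_spec(float(target), float(radius), direction=direction))
            params = PipelineParams(alpha=0.0, tcl_threshold=0.0, dilation_radius=TEST_DILATION_PX)
            _, cands = detect_epe(case.p_ca, case.prostate, params)
            measured = max(c.contact_length_mm for c in cands if c.crosses_capsule)
            assert abs(measured - case.lesions[0].contact_mm) <= tol_mm

    def test_alpha_aware_oracle_shrinks(self, straddling_case):
        les = straddling_case.lesions[0]
        full = oracle_contact_length(straddling_case, les, 0.0)
        at_op = oracle_contact_length(straddling_case, les, 0.30)
        assert full == pytest.approx(les.contact_mm)
        assert 0 < at_op < full


class TestMakeCohort:
    def test_reproducible_and_prefix_stable(self):
        a = make_cohort(4, 0.5, seed=3, shape=(64, 64, 8), spacing=(0.5, 0.5, 3.0))
        b = make_cohort(4, 0.5, seed=3, shape=(64, 64, 8), spacing=(0.5, 0.5, 3.0))
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.p_ca.data, cb.p_ca.data)
        # case k is independent of cohort size
        c = make_cohort(2, 0.5, seed=3, shape=(64, 64, 8), spacing=(0.5, 0.5, 3.0))
        assert np.array_equal(a[1].p_ca.data, c[1].p_ca.data)

    def test_zero_prevalence_all_negative(self):
        cohort = make_cohort(6, 0.0, seed=1, shape=(64, 64, 8), spacing=(0.5, 0.5, 3.0))
        assert all(not case.gt_epe.data.any() for case in cohort)

    def test_observed_prevalence_within_binomial_error(self):
        n = 40
        cohort = make_cohort(n, 0.5, seed=5, shape=(64, 64, 8), spacing=(0.5, 0.5, 3.0))
        k = sum(bool(case.gt_epe.data.any()) for case in cohort)
        # 3 sigma of Binomial(40, 0.5) is ~9.5
        assert abs(k - 20) <= 10

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(0, 0.5)
        with pytest.raises(ValueError):
            make_cohort(2, 1.5)
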