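import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epedetect.evaluation import (
    DEFAULT_ALPHA_GRID,
    DEFAULT_TCL_GRID,
    ConfusionCounts,
    EvalCase,
    auc,
    confusion,
    grid_search_tcl,
    patient_call,
    roc_sweep,
    sens_spec,
)
from epedetect.epe_pipeline import PipelineParams
from epedetect.phantom import LesionSpec, make_case
from epedetect.volio import Volume3D

from conftest import TEST_DILATION_PX, simple_spec, straddle_spec


def _prob(data, spacing=(0.5, 0.5, 3.0)):
    return Volume3D(np.asarray(data, dtype=float), spacing, kind="probability")


class TestPatientCall:
    def test_all_zero_negative(self):
        assert not patient_call(_prob(np.zeros((4, 4, 2))))

    def test_single_voxel_positive(self):
        data = np.zeros((4, 4, 2))
        data[1, 2, 0] = 0.4
        assert patient_call(_prob(data))


class TestConfusion:
    def test_all_correct_positive(self):
        c = confusion([True] * 4, [True] * 4)
        assert (c.tp, c.fp, c.tn, c.fn) == (4, 0, 0, 0)

    def test_all_missed(self):
        c = confusion([False] * 4, [True] * 4)
        assert c.fn == 4 and c.total == 4

    def test_sextant_example_two_positive(self):
        gt = [True, False, True, False, False, False]
        pred = [True, False, True, False, False, False]
        c = confusion(pred, gt)
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 4, 0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([True], [True, False])


class TestSensSpec:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(tp=2, fn=0, tn=4, fp=0), (1.0, 1.0)),
            (ConfusionCounts(tp=2, fn=0, tn=2, fp=2), (1.0, 0.5)),
            (ConfusionCounts(tp=0, fn=1, tn=0, fp=1), (0.0, 0.0)),
        ],
    )
    def test_values(self, counts, expected):
        assert sens_spec(counts) == expected

    def test_undefined_components_are_none(self):
        sens, spec = sens_spec(ConfusionCounts(tp=0, fn=0, tn=3, fp=1))
        assert sens is None and spec == 0.75


class TestAuc:
    def test_perfect_corner(self):
        assert auc([(0.0, 1.0)]) == 1.0

    def test_single_midpoint(self):
        assert auc([(0.5, 0.5)]) == 0.5

    def test_diagonal_points(self):
        pts = [(0.2, 0.2), (0.4, 0.4), (0.9, 0.9)]
        assert auc(pts) == pytest.approx(0.5)

    def test_order_invariant(self):
        pts = [(0.1, 0.6), (0.7, 0.9), (0.3, 0.8)]
        assert auc(pts) == auc(list(reversed(pts)))

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
            ),
            min_size=1,
            max_size=12,
        ),
        st.randoms(use_true_random=False),
    )
    def test_permutation_invariant_and_bounded(self, pts, rnd):
        """AUC is invariant to input ordering and always lies in [0, 1]."""
        a = auc(pts)
        shuffled = list(pts)
        rnd.shuffle(shuffled)
        assert auc(shuffled) == a
        assert 0.0 <= a <= 1.0


class TestDefaults:
    def test_alpha_grid_21_points(self):
        assert len(DEFAULT_ALPHA_GRID) == 21
        assert DEFAULT_ALPHA_GRID[0] == 0.0 and DEFAULT_ALPHA_GRID[-1] == 1.0
        assert np.allclose(np.diff(DEFAULT_ALPHA_GRID), 0.05)

    def test_tcl_grid_values(self):
        assert DEFAULT_TCL_GRID == (2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0)


def _separable_cohort():
    """2 positives with strong straddling lesions, 2 empty negatives."""
    cases = []
    for seed in (1, 2):
        case = make_case(straddle_spec(14.0, 9.0, peak=0.9, seed=seed))
        cases.append(case.as_eval_case(f"pos{seed}"))
    for seed in (3, 4):
        case = make_case(simple_spec([], seed=seed))
        cases.append(case.as_eval_case(f"neg{seed}"))
    return cases


class TestRocSweep:
    def test_perfectly_separating_cohort_patient_auc_one(self):
        params = PipelineParams(tcl_threshold=10.0, dilation_radius=TEST_DILATION_PX)
        grid = (0.0, 0.25, 0.5, 0.75, 1.0)
        roc_pat, roc_sex = roc_sweep(_separable_cohort(), grid, params)
        assert roc_pat.auc == pytest.approx(1.0)
        assert len(roc_pat.points) == len(grid)

    def test_single_class_cohort_auc_absent(self):
        params = PipelineParams(tcl_threshold=10.0, dilation_radius=TEST_DILATION_PX)
        cases = [make_case(simple_spec([], seed=s)).as_eval_case(str(s)) for s in (1, 2)]
        roc_pat, _ = roc_sweep(cases, (0.0, 0.5, 1.0), params)
        assert roc_pat.auc is None


class TestGridSearchTcl:
    def test_single_case_single_tcl_one_row(self):
        params = PipelineParams(dilation_radius=TEST_DILATION_PX)
        table = grid_search_tcl(_separable_cohort(), [10.0], (0.0, 0.5, 1.0), params)
        assert len(table) == 1
        assert set(table.columns) == {"tcl_mm", "patient_auc", "sextant_auc"}

    def test_zero_tcl_auc_at_least_large_tcl(self):
        """With every positive lesion's contact above the threshold range
        tested, lowering the threshold can only help."""
        params = PipelineParams(dilation_radius=TEST_DILATION_PX)
        grid = (0.0, 0.3, 0.6, 1.0)
        table = grid_search_tcl(_separable_cohort(), [0.0, 30.0], grid, params)
        assert table.patient_auc.iloc[0] >= table.patient_auc.iloc[1]
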