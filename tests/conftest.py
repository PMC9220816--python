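"""Shared fixtures: small phantom cases and cohorts sized for fast tests.

Test grids are 128x128x10 voxels at 0.5 mm in-plane / 3 mm slice spacing
(a scaled-down version of the 224x224 @ 0.29 mm study grid); the dilation
radius is 19 px so the dilated search region spans the same ~9.5 mm
physical margin.
"""

from __future__ import annotations

import numpy as np
import pytest

from epedetect import (
    LesionSpec,
    PhantomSpec,
    PipelineParams,
    make_case,
    make_cohort,
)

TEST_SHAPE = (128, 128, 10)
TEST_SPACING = (0.5, 0.5, 3.0)
TEST_SEMI_AXES = (16.0, 13.0, 12.0)
TEST_DILATION_PX = 19  # 9.5 mm at 0.5 mm/px


def simple_spec(lesions, noise=0.0, seed=1, semi_axes=TEST_SEMI_AXES, shape=TEST_SHAPE):
    return PhantomSpec(
        shape=shape,
        spacing=TEST_SPACING,
        semi_axes_mm=semi_axes,
        lesions=lesions,
        noise_amplitude=noise,
        seed=seed,
    )


def straddle_spec(target_mm, radius_mm, peak=0.9, contact_alpha=0.0, direction=90.0, **kw):
    return simple_spec(
        [
            LesionSpec(
                radius_mm=radius_mm,
                peak=peak,
                placement="straddling",
                target_contact_mm=target_mm,
                contact_alpha=contact_alpha,
                direction_deg=direction,
            )
        ],
        **kw,
    )


@pytest.fixture(scope="session")
def straddling_case():
    """One noiseless case whose lesion has a 14 mm contact arc at the
    alpha = 0.30 operating point (the support the pipeline thresholds)."""
    return make_case(straddle_spec(14.0, 13.0, contact_alpha=0.30))


@pytest.fixture(scope="session")
def test_params():
    return PipelineParams(alpha=0.30, tcl_threshold=10.0, dilation_radius=TEST_DILATION_PX)


@pytest.fixture(scope="session")
def cohort20():
    """20-case mixed cohort with default phantom noise, for sweep tests."""
    return make_cohort(
        20, epe_prevalence=0.5, seed=11, shape=TEST_SHAPE, spacing=TEST_SPACING
    )


@pytest.fixture(scope="session")
def cohort20_sweep(cohort20, test_params):
    """Per-case patient predictions over the full alpha grid, plus GT."""
    from epedetect.evaluation import DEFAULT_ALPHA_GRID, sweep_case_predictions

    per_case = [
        sweep_case_predictions(c.p_ca, c.prostate, test_params, DEFAULT_ALPHA_GRID)[0]
        for c in cohort20
    ]
    gt = [bool(c.gt_epe.data.any()) for c in cohort20]
    return per_case, gt
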