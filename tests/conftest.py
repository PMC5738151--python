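import numpy as np
import pytest

from posturemetrics import (
    FrontalTruth,
    SagittalTruth,
    generate_frontal_views,
    generate_sagittal_view,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def left_view():
    """Noise-free LEFT profile view with the default (cohort-mean) truth."""
    return generate_sagittal_view(SagittalTruth(), side="LEFT")


@pytest.fixture
def symmetric_front_back():
    """Perfectly symmetric FRONT and BACK views (all asymmetries zero)."""
    return generate_frontal_views(FrontalTruth())


@pytest.fixture
def asymmetric_truth():
    """The hand-evaluated asymmetry example: total index 16.0909..."""
    return FrontalTruth(
        trunk_height_e=50.0,
        ref_offset=2.0,
        width_axilla_left=12.0,
        width_axilla_right=10.0,
        width_waist_left=15.0,
        width_waist_right=15.0,
        dh_shoulder=1.0,
        dh_axilla=0.5,
        dh_waist=0.0,
    )
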