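import numpy as np
import pytest

from pbmshape.curve_io import RaterTrace, ScanMeta
from pbmshape.synthetic_data import SynthParams, simulate_cohort


@pytest.fixture
def meta_od():
    return ScanMeta(subject_id="S1", eye="OD", angle_deg=0,
                    lateral_scale=6.0, axial_scale=3.9, width_px=1024)


@pytest.fixture
def meta_os():
    return ScanMeta(subject_id="S1", eye="OS", angle_deg=0,
                    lateral_scale=6.0, axial_scale=3.9, width_px=1024)


def make_trace(rater_id="R1", y_offset=0.0, width=1024, margin_left=400, margin_right=624,
               y_fn=None):
    """Flat (or y_fn-shaped) two-branch pixel trace spanning the full image."""
    xl = np.arange(0, margin_left + 1, dtype=float)
    xr = np.arange(margin_right, width, dtype=float)
    f = y_fn if y_fn is not None else (lambda x: np.full_like(x, 100.0))
    return RaterTrace(
        rater_id=rater_id,
        branches=(
            np.column_stack([xl, f(xl) + y_offset]),
            np.column_stack([xr, f(xr) + y_offset]),
        ),
        margin_x_px=np.array([float(margin_left), float(margin_right)]),
    )


@pytest.fixture
def flat_traces():
    return [make_trace("R1"), make_trace("R2")]


@pytest.fixture(scope="session")
def small_cohort():
    """Five-subject default-parameter cohort shared across tests."""
    return simulate_cohort(SynthParams(n_subjects=5, seed=42))


@pytest.fixture(scope="session")
def noiseless_params():
    return SynthParams(
        n_subjects=3,
        curve_noise_sd=0.0,
        rater_noise_sd_outer=0.0,
        rater_noise_sd_central=0.0,
        seed=7,
    )
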