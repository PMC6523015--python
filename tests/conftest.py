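import numpy as np
import pytest

from arcqa.dose_model import ConeKernel
from arcqa.geometry import build_arccheck_geometry
from arcqa.pipeline import build_study
from arcqa.plan_model import generate_body_path_plan


@pytest.fixture(scope="session")
def array():
    return build_arccheck_geometry()


@pytest.fixture(scope="session")
def kernel():
    return ConeKernel()


@pytest.fixture(scope="session")
def small_plan():
    """A cheap 24-beam plan for unit tests."""
    return generate_body_path_plan(n_beams=24, seed=7)


@pytest.fixture(scope="session")
def study():
    """The full default study: 116-beam plan, selection LUT, curves."""
    return build_study(plan_seed=0)
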