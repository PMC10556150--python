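"""Shared fixtures: small synthetic cohorts generated at test time."""
from __future__ import annotations

import numpy as np
import pytest

from dfnckit import SlidingWindowConnectivity, SyntheticSpec, WindowSpec, make_cohort


@pytest.fixture(scope="session")
def tiny_window_spec() -> WindowSpec:
    # short windows keep per-test graphical-lasso work negligible
    return WindowSpec(width_tr=20, step_tr=2)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_window_spec):
    """3 + 3 subjects, 100 timepoints: fast end-to-end substrate."""
    spec = SyntheticSpec(n_group_a=3, n_group_b=3, n_timepoints=100, seed=7)
    return make_cohort(spec, tiny_window_spec)


@pytest.fixture(scope="session")
def tiny_series(tiny_cohort, tiny_window_spec):
    sw = SlidingWindowConnectivity(
        width_tr=tiny_window_spec.width_tr, step_tr=tiny_window_spec.step_tr
    ).fit()
    return sw.transform(tiny_cohort.timecourses)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
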