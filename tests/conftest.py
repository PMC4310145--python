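"""Shared fixtures.

Expensive end-to-end analyses (fit + all profiles) are session-scoped so
property tests and acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from plsdesign.estimation import fit_mle
from plsdesign.profiling import confidence_interval, profile_all, profile_samples
from plsdesign.synthetic_data import make_fixture


@pytest.fixture(scope="session")
def insilico_baseline():
    return make_fixture("insilico_baseline")


@pytest.fixture(scope="session")
def insilico_fit(insilico_baseline):
    fx = insilico_baseline
    return fit_mle(fx.model, fx.data, fx.design, start=fx.truth, n_starts=20, seed=1)


@pytest.fixture(scope="session")
def insilico_curves(insilico_baseline, insilico_fit):
    fx = insilico_baseline
    return profile_all(fx.model, fx.data, fx.design, insilico_fit)


@pytest.fixture(scope="session")
def insilico_intervals(insilico_curves):
    return {p: confidence_interval(c) for p, c in insilico_curves.items()}


@pytest.fixture(scope="session")
def insilico_samples(insilico_curves):
    return {p: profile_samples(c) for p, c in insilico_curves.items()}


@pytest.fixture(scope="session")
def dsalina_model():
    from plsdesign.models_library import build_dsalina_model

    return build_dsalina_model()


@pytest.fixture(scope="session")
def prediction_grid(insilico_baseline):
    t = np.asarray(insilico_baseline.design.times)
    return np.linspace(t[0], t[-1], 101)
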