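"""Simulation, readouts, stimuli and interventions."""

import numpy as np
import pytest

from plsdesign.model_core import (
    ConfigurationError,
    ExperimentDesign,
    Intervention,
    StimulusProfile,
    apply_intervention,
    evaluate_readout,
    simulate,
)
from plsdesign.models_library import (
    build_dsalina_model,
    build_insilico_model,
    reference_params,
)

PULSE_166 = StimulusProfile("pulse", 166.0, 0.0, 1.0)
DSALINA_GRID = np.logspace(-4, 0, 120)


def _design(observed, stimulus, times=(1.0,)):
    return ExperimentDesign(observed=observed, stimulus=stimulus, times=times)


class TestSimulate:
    def test_no_stimulus_no_source_stays_zero(self):
        model = build_insilico_model()
        params = reference_params("insilico4")
        design = _design(("D",), StimulusProfile("constant", 0.0))
        traj = simulate(model, params, design, np.linspace(0, 5, 20))
        assert np.allclose(traj.values, 0.0, atol=1e-12)

    def test_dsalina_dark_fluorescence_is_zero(self):
        model = build_dsalina_model()
        params = reference_params("dsalina")
        design = _design(("F",), StimulusProfile("constant", 0.0))
        traj = simulate(model, params, design, DSALINA_GRID)
        assert np.allclose(traj.state("x1"), 0.0, atol=1e-9)
        F = evaluate_readout(model, traj, params, "F")
        assert np.allclose(F, 0.0, atol=1e-9)

    def test_dsalina_induction_rises_and_saturates(self):
        # normalized fluorescence climbs >= 2 orders of magnitude from the
        # first sample and flattens near the end of the 1 s pulse
        model = build_dsalina_model()
        params = reference_params("dsalina")
        design = _design(("F",), PULSE_166)
        traj = simulate(model, params, design, DSALINA_GRID)
        F = evaluate_readout(model, traj, params, "F")
        assert F[0] < F.max() / 100
        assert F.max() == pytest.approx(F[-1], rel=0.05)  # plateau at pulse end
        late = F[DSALINA_GRID > 0.5]
        assert np.max(late) - np.min(late) < 0.05 * F.max()

    def test_dsalina_state_bounds_probability_semantics(self):
        model = build_dsalina_model()
        params = reference_params("dsalina")
        p = params.to_linear()
        design = _design(("F",), PULSE_166)
        traj = simulate(model, params, design, DSALINA_GRID)
        tol = 1e-6
        x1, x2, x3, x4, x5 = (traj.state(s) for s in model.state_labels)
        assert np.all(x1 >= -tol) and np.all(x1 <= 290.0 + tol)
        assert np.all(x2 >= -tol) and np.all(x2 <= 1.0 + tol)
        assert np.all(x3 >= -tol) and np.all(x4 >= -tol)
        assert np.all(x3 + x4 <= p["r2"] + tol)
        assert np.all(x5 >= -tol) and np.all(x5 <= p["PQ0"] + tol)

    def test_determinism(self):
        model = build_dsalina_model()
        params = reference_params("dsalina")
        design = _design(("F",), PULSE_166)
        a = simulate(model, params, design, DSALINA_GRID)
        b = simulate(model, params, design, DSALINA_GRID)
        assert np.array_equal(a.values, b.values)

    def test_tolerance_refinement_converges(self):
        model = build_dsalina_model()
        params = reference_params("dsalina")
        design = _design(("F",), PULSE_166)
        coarse = simulate(model, params, design, DSALINA_GRID, rtol=1e-6, atol=1e-8)
        fine = simulate(model, params, design, DSALINA_GRID, rtol=1e-7, atol=1e-9)
        Fc = evaluate_readout(model, coarse, params, "F")
        Ff = evaluate_readout(model, fine, params, "F")
        assert np.max(np.abs(Fc - Ff)) < 10 * 1e-6 * np.max(np.abs(Ff)) + 10 * 1e-8

    def test_insilico_closed_form_matches_integrator(self):
        model = build_insilico_model()
        params = reference_params("insilico4")
        design = _design(("D",), StimulusProfile("pulse", 1.0, 0.0, 1.0))
        grid = np.linspace(0, 2.5, 40)
        closed = simulate(model, params, design, grid)
        model.linear_system = None
        numeric = simulate(model, params, design, grid)
        assert np.max(np.abs(closed.values - numeric.values)) < 1e-6

    def test_invalid_grid_rejected(self):
        model = build_insilico_model()
        params = reference_params("insilico4")
        design = _design(("D",), StimulusProfile("constant", 1.0))
        with pytest.raises(ConfigurationError):
            simulate(model, params, design, np.array([1.0, 0.5]))


class TestReadouts:
    def test_identity_readout_returns_state(self):
        model = build_insilico_model()
        params = reference_params("insilico4")
        design = _design(("B",), StimulusProfile("constant", 1.0))
        traj = simulate(model, params, design, np.linspace(0, 3, 10))
        assert np.array_equal(evaluate_readout(model, traj, params, "B"), traj.state("B"))

    def test_fluorescence_gain_arithmetic(self, dsalina_model):
        # F = G k2 x1: G=1e-2, k2=10, x1=3 -> 0.3
        params = reference_params("dsalina").with_value("G", -2.0).with_value("k2", 1.0)
        states = {lab: np.zeros(1) for lab in dsalina_model.state_labels}
        states["x1"] = np.array([3.0])
        F = dsalina_model.readouts["F"](states, params.to_linear())
        assert F[0] == pytest.approx(0.3, rel=1e-12)

    def test_unknown_readout_is_configuration_error(self):
        model = build_insilico_model()
        params = reference_params("insilico4")
        design = _design(("D",), StimulusProfile("constant", 1.0))
        traj = simulate(model, params, design, np.linspace(0, 1, 5))
        with pytest.raises(ConfigurationError):
            evaluate_readout(model, traj, params, "nope")


class TestIntervention:
    def test_log10_arithmetic(self):
        params = reference_params("insilico4")
        out = apply_intervention(params, Intervention("k21", 1e-4))
        assert out["k21"] == pytest.approx(0.398 - 4.0, abs=1e-12)
        assert params["k21"] == 0.398  # original untouched

    def test_factor_one_is_identity(self):
        params = reference_params("insilico4")
        assert apply_intervention(params, Intervention("d", 1.0)) == params

    def test_twice_equals_squared_factor(self):
        params = reference_params("insilico4")
        once = apply_intervention(params, Intervention("k11", 1e-2))
        twice = apply_intervention(once, Intervention("k11", 1e-2))
        direct = apply_intervention(params, Intervention("k11", 1e-4))
        assert np.allclose(twice.values, direct.values)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ConfigurationError):
            Intervention("k11", 0.0)

    def test_simulation_applies_intervention(self):
        # inhibiting the only route into B suppresses B by orders of magnitude
        model = build_insilico_model()
        params = reference_params("insilico4")
        base = _design(("B",), StimulusProfile("constant", 1.0))
        inhibited = base.with_interventions((Intervention("k11", 1e-4),))
        grid = np.linspace(0, 3, 10)
        b0 = simulate(model, params, base, grid).state("B")
        b1 = simulate(model, params, inhibited, grid).state("B")
        assert np.max(b1) < 1e-3 * np.max(b0)
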