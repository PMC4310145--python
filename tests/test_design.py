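"""Candidate enumeration, Pareto ranking and anticipatory experiments."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plsdesign.design import (
    CriterionPoint,
    DesignCandidate,
    anticipatory_experiment,
    enumerate_candidates,
    evaluate_design,
    pareto_front,
    score_candidates,
)
from plsdesign.model_core import ExperimentDesign, StimulusProfile
from plsdesign.models_library import build_insilico_model
from plsdesign.synthetic_data import NoiseSpec


@pytest.fixture
def base_design():
    return ExperimentDesign(
        observed=("D",),
        stimulus=StimulusProfile("pulse", 1.0, 0.0, 1.0),
        times=tuple(np.linspace(0, 2.5, 16)),
    )


class TestEnumerate:
    def test_readout_candidates_are_unmeasured_states(self, base_design):
        model = build_insilico_model()
        cands = enumerate_candidates(model, base_design)
        assert [c.id for c in cands] == ["readout:A", "readout:B", "readout:C"]

    def test_six_single_inhibitions(self, base_design):
        model = build_insilico_model()
        cands = enumerate_candidates(
            model, base_design, max_added_readouts=0, allow_inhibitions=True
        )
        assert len(cands) == 6
        assert all(c.id.startswith("inhibit:") for c in cands)
        assert all(c.interventions[0].factor == 1e-4 for c in cands)

    def test_nothing_to_add_warns_and_returns_empty(self):
        model = build_insilico_model()
        full = ExperimentDesign(
            observed=("A", "B", "C", "D"),
            stimulus=StimulusProfile("constant", 1.0),
            times=(1.0, 2.0),
        )
        with pytest.warns(UserWarning, match="no design candidates"):
            assert enumerate_candidates(model, full) == []

    def test_candidate_must_modify_design(self):
        with pytest.raises(ValueError):
            DesignCandidate(id="noop")


class TestPareto:
    def test_single_candidate_trivially_optimal(self):
        pts = pareto_front([CriterionPoint("a", 1.0, 1.0)])
        assert pts[0].pareto

    def test_strict_domination(self):
        pts = pareto_front(
            [CriterionPoint("big", 2.0, 2.0), CriterionPoint("small", 1.0, 1.0)]
        )
        flags = {p.candidate_id: p.pareto for p in pts}
        assert flags == {"big": True, "small": False}

    def test_trade_off_keeps_both(self):
        pts = pareto_front(
            [CriterionPoint("s", 2.0, 1.0), CriterionPoint("j", 1.0, 2.0)]
        )
        assert all(p.pareto for p in pts)

    @given(
        st.lists(
            st.tuples(st.floats(0, 10), st.floats(0, 10)),
            min_size=1, max_size=12,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_n_squared(self, coords):
        pts = pareto_front(
            [CriterionPoint(str(i), s, j) for i, (s, j) in enumerate(coords)]
        )
        for p in pts:
            dominated = any(
                (q.s_tot >= p.s_tot and q.J_tot >= p.J_tot)
                and (q.s_tot > p.s_tot or q.J_tot > p.J_tot)
                for q in pts
            )
            assert p.pareto == (not dominated)


class TestScoring:
    def test_readout_coordinates_come_from_base_summary(
        self, insilico_baseline, insilico_fit, insilico_samples, prediction_grid
    ):
        from plsdesign.pls import pls_summary

        fx = insilico_baseline
        summ = pls_summary(
            fx.model, insilico_samples, fx.design, insilico_fit.theta_hat,
            ("A", "B", "C", "D"), prediction_grid,
        )
        cands = enumerate_candidates(fx.model, fx.design)
        points = score_candidates(fx.model, cands, summ)
        by_id = {p.candidate_id: p for p in points}
        for state in ("A", "B", "C"):
            assert by_id[f"readout:{state}"].s_tot == pytest.approx(summ[state].s_tot)
            assert by_id[f"readout:{state}"].J_tot == pytest.approx(summ[state].J_tot)

    def test_missing_summary_raises(self, insilico_baseline):
        fx = insilico_baseline
        cands = enumerate_candidates(fx.model, fx.design)
        with pytest.raises(KeyError):
            score_candidates(fx.model, cands, {})


class TestAnticipatory:
    def test_zero_noise_equals_mle_simulation(self, insilico_baseline, insilico_fit):
        fx = insilico_baseline
        cand = DesignCandidate(id="readout:B", added_readouts=("B",))
        data = anticipatory_experiment(
            fx.model, insilico_fit, cand, fx.design,
            NoiseSpec(0.0, 0.0, allow_exact=True), seed=5,
        )
        from plsdesign.estimation import predict_dataset

        design = ExperimentDesign(
            observed=("B",), stimulus=fx.design.stimulus, times=fx.design.times
        )
        pred = predict_dataset(fx.model, insilico_fit.theta_hat, design, data)
        assert np.allclose(data.table["mean"].to_numpy(), pred["B"], atol=1e-9)

    def test_seed_reproducibility(self, insilico_baseline, insilico_fit):
        fx = insilico_baseline
        cand = DesignCandidate(id="readout:A", added_readouts=("A",))
        a = anticipatory_experiment(
            fx.model, insilico_fit, cand, fx.design, NoiseSpec(), seed=7
        )
        b = anticipatory_experiment(
            fx.model, insilico_fit, cand, fx.design, NoiseSpec(), seed=7
        )
        c = anticipatory_experiment(
            fx.model, insilico_fit, cand, fx.design, NoiseSpec(), seed=8
        )
        assert np.array_equal(a.table["mean"], b.table["mean"])
        assert not np.array_equal(a.table["mean"], c.table["mean"])
        assert a.provenance == "synthetic:7"


class TestEvaluateDesign:
    def test_informative_augmentation_gains_identifiability(
        self, insilico_baseline, insilico_fit, insilico_intervals
    ):
        # observing every state almost noise-free must strictly improve on
        # the D-only baseline (0 identifiable) and cannot widen the one
        # finite bound the baseline has (information monotonicity)
        fx = insilico_baseline
        cand = DesignCandidate(id="readout:A+B+C", added_readouts=("A", "B", "C"))
        extra = anticipatory_experiment(
            fx.model, insilico_fit, cand, fx.design, NoiseSpec(0.0, 0.01), seed=3
        )
        ev = evaluate_design(
            fx.model, fx.data.merge(extra), cand, fx.design,
            start=insilico_fit.theta_hat, n_starts=2, seed=1,
        )
        base_count = sum(ci.identifiable for ci in insilico_intervals.values())
        assert ev.identifiable_count >= max(base_count, 3)
        assert ev.intervals["d"].upper <= insilico_intervals["d"].upper + 1e-2
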