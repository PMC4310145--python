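"""Experimental-design candidate enumeration, scoring and evaluation.

Candidates are modifications of a base experiment: new readouts picked
from the unmeasured states, single-parameter inhibitions (a rate
constant scaled down by a small factor to emulate an inhibitor), or
combinations of both. Each candidate is scored in the two-dimensional
criterion space

    O = [s_tot, J_tot]^T,

where s_tot is the total PLS index of the candidate's prediction (how
much parameter uncertainty it would expose) and J_tot the PLS entropy
(how evenly that uncertainty is spread over the parameters). Both are
maximized; since they generally conflict, candidates are ranked by
Pareto nondomination rather than a scalar score.

Beyond the cheap criterion-space scoring, a candidate can be evaluated
*anticipatorily*: simulate the candidate experiment at the current MLE,
add noise, merge the synthetic data with the real data, refit and
re-profile every parameter — the identifiability actually gained.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .estimation import Dataset, FitResult, fit_mle
from .model_core import DynamicModel, ExperimentDesign, Intervention
from .parameters import Log10ParameterVector
from .pls import PLSResult, pls_summary
from .profiling import (
    ConfidenceInterval,
    ProfilePolicy,
    confidence_interval,
    profile_all,
)

__all__ = [
    "DesignCandidate",
    "CriterionPoint",
    "DesignEvaluation",
    "enumerate_candidates",
    "score_candidates",
    "pareto_front",
    "anticipatory_experiment",
    "evaluate_design",
]

DEFAULT_INHIBITION_FACTOR = 1e-4


@dataclass(frozen=True)
class DesignCandidate:
    """A proposed modification of the base experiment."""

    id: str
    added_readouts: tuple[str, ...] = ()
    interventions: tuple[Intervention, ...] = ()

    def __post_init__(self):
        if not self.added_readouts and not self.interventions:
            raise ValueError("candidate must modify the base design")


@dataclass
class CriterionPoint:
    """A candidate's coordinates in (s_tot, J_tot) criterion space."""

    candidate_id: str
    s_tot: float
    J_tot: float
    pareto: bool = False


@dataclass
class DesignEvaluation:
    """Anticipatory evaluation: identifiability after the new experiment."""

    candidate_id: str
    intervals: dict[str, ConfidenceInterval]
    fit: FitResult
    curves: dict = field(default_factory=dict)

    @property
    def identifiable_count(self) -> int:
        return sum(ci.identifiable for ci in self.intervals.values())


def enumerate_candidates(
    model: DynamicModel,
    base: ExperimentDesign,
    max_added_readouts: int = 1,
    allow_inhibitions: bool = False,
    inhibition_factor: float = DEFAULT_INHIBITION_FACTOR,
    combinations: bool = False,
) -> list[DesignCandidate]:
    """All single additions (and optionally pairwise combinations).

    Readout candidates are the model states not in the base design;
    inhibition candidates target each model parameter. Ordering is
    deterministic (sorted by candidate id).
    """
    unmeasured = [s for s in model.state_labels if s not in base.observed]
    out: list[DesignCandidate] = []
    if max_added_readouts >= 1:
        for s in unmeasured:
            out.append(DesignCandidate(id=f"readout:{s}", added_readouts=(s,)))
        for combo in itertools.combinations(unmeasured, 2):
            if max_added_readouts >= 2:
                out.append(
                    DesignCandidate(id="readout:" + "+".join(combo), added_readouts=combo)
                )
    if allow_inhibitions:
        for p in model.param_labels:
            out.append(
                DesignCandidate(
                    id=f"inhibit:{p}",
                    interventions=(Intervention(p, inhibition_factor),),
                )
            )
        if combinations:
            for s in unmeasured:
                for p in model.param_labels:
                    out.append(
                        DesignCandidate(
                            id=f"readout:{s}+inhibit:{p}",
                            added_readouts=(s,),
                            interventions=(Intervention(p, inhibition_factor),),
                        )
                    )
    if not out:
        import warnings

        warnings.warn("no design candidates: all states measured, inhibitions disallowed")
    return sorted(out, key=lambda c: c.id)


def pareto_front(points: list[CriterionPoint]) -> list[CriterionPoint]:
    """Flag nondominated points (both coordinates maximized); returns input."""
    for p in points:
        p.pareto = not any(
            (q.s_tot >= p.s_tot and q.J_tot >= p.J_tot)
            and (q.s_tot > p.s_tot or q.J_tot > p.J_tot)
            for q in points
        )
    return points


def score_candidates(
    model: DynamicModel,
    candidates: list[DesignCandidate],
    base_summaries: dict[str, PLSResult],
    sample_sets=None,
    base_design: ExperimentDesign | None = None,
    theta_hat: Log10ParameterVector | None = None,
    times: np.ndarray | None = None,
    rtol: float | None = None,
    atol: float | None = None,
) -> list[CriterionPoint]:
    """Coordinates of each candidate in criterion space.

    A pure readout candidate reuses the base analysis: its coordinates
    are the (s_tot, J_tot) of predicting that state under the base
    design. A candidate with interventions changes the dynamics, so its
    ensembles are re-simulated under the inhibited parameter set (same
    profile samples; the samples encode the current data's uncertainty,
    the intervention changes what an experiment would reveal).
    """
    points = []
    for cand in candidates:
        if not cand.interventions:
            missing = [r for r in cand.added_readouts if r not in base_summaries]
            if missing:
                raise KeyError(f"no base PLS summary for readouts {missing}")
            s_tot = sum(base_summaries[r].s_tot for r in cand.added_readouts)
            J_tot = sum(base_summaries[r].J_tot for r in cand.added_readouts)
        else:
            if sample_sets is None or base_design is None or theta_hat is None:
                raise ValueError(
                    "intervention candidates need sample_sets, base_design and theta_hat"
                )
            design = base_design.with_interventions(cand.interventions)
            preds = cand.added_readouts or base_design.observed
            t = times if times is not None else np.asarray(base_design.times)
            summ = pls_summary(
                model, sample_sets, design, theta_hat, preds, t, rtol=rtol, atol=atol
            )
            s_tot = sum(r.s_tot for r in summ.values())
            J_tot = sum(r.J_tot for r in summ.values())
        points.append(CriterionPoint(cand.id, float(s_tot), float(J_tot)))
    return pareto_front(points)


def anticipatory_experiment(
    model: DynamicModel,
    fit: FitResult,
    candidate: DesignCandidate,
    base_design: ExperimentDesign,
    noise,
    seed: int,
    times: np.ndarray | None = None,
) -> Dataset:
    """Generate the in-silico dataset a candidate experiment would yield.

    Simulates the candidate design at the current MLE and adds Gaussian
    noise per ``noise`` (a NoiseSpec); the returned Dataset is tagged
    ``synthetic:<seed>`` and is meant to be merged with the real data.
    """
    from .synthetic_data import generate_dataset

    t = np.asarray(times if times is not None else base_design.times, dtype=float)
    observed = candidate.added_readouts or base_design.observed
    design = ExperimentDesign(
        observed=observed,
        stimulus=base_design.stimulus,
        times=tuple(t),
        interventions=base_design.interventions + candidate.interventions,
    )
    return generate_dataset(model, fit.theta_hat, design, t, noise, seed)


def evaluate_design(
    model: DynamicModel,
    merged_data: Dataset,
    candidate: DesignCandidate,
    base_design: ExperimentDesign,
    start: Log10ParameterVector,
    policy: ProfilePolicy = ProfilePolicy(),
    n_starts: int = 2,
    seed: int = 0,
    rtol: float | None = None,
    atol: float | None = None,
) -> DesignEvaluation:
    """Refit and re-profile every parameter on the merged dataset."""
    design = ExperimentDesign(
        observed=tuple(dict.fromkeys(base_design.observed + candidate.added_readouts)),
        stimulus=base_design.stimulus,
        times=base_design.times,
        interventions=base_design.interventions + candidate.interventions,
    )
    missing = [r for r in design.observed if r not in merged_data.readouts()]
    if missing:
        raise ValueError(f"merged data lacks readouts {missing}")
    fit = fit_mle(
        model, merged_data, design, start=start, n_starts=n_starts, seed=seed,
        rtol=rtol, atol=atol,
    )
    curves = profile_all(
        model, merged_data, design, fit, policy, rtol=rtol, atol=atol
    )
    intervals = {
        p: confidence_interval(c, alpha=policy.alpha, df=policy.df)
        for p, c in curves.items()
    }
    return DesignEvaluation(
        candidate_id=candidate.id, intervals=intervals, fit=fit, curves=curves
    )
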