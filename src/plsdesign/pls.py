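"""Profile-likelihood sensitivity (PLS) indices and entropy.

Given parameter vectors sampled along the profile likelihood of each
parameter theta_i, every sample is propagated through the model to give
an ensemble of trajectories for a prediction p (a state or readout).
The PLS index of theta_i for p at time t_k is the squared normalized
ensemble spread

    s_i(t_k) = ( (max{p_i(t_k)} - min{p_i(t_k)}) / <p_hat(t)>_t )^2,

where <p_hat(t)>_t is the time average of the prediction at the MLE.
Summing over parameters and times gives the total index

    s_tot = sum_i sum_k s_i(t_k),

and Shannon's entropy of the per-time normalized indices

    s~_i(t_k) = s_i(t_k) / sum_i s_i(t_k),
    J_k  = sum_i -s~_i(t_k) * log(s~_i(t_k)),      J_tot = sum_k J_k

measures how homogeneously the parameters contribute to the prediction
uncertainty (natural log; J_k in [0, ln n_theta]). s_tot and J_tot are
the two coordinates of the experimental-design criterion space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .model_core import (
    DynamicModel,
    ExperimentDesign,
    SimulationError,
    evaluate_readout,
    simulate,
)
from .parameters import Log10ParameterVector
from .profiling import ParameterSampleSet

__all__ = [
    "PredictionEnsemble",
    "PLSResult",
    "prediction_ensemble",
    "pls_index",
    "pls_total",
    "pls_entropy",
    "pls_summary",
]

logger = logging.getLogger(__name__)

DEGENERATE_MEAN = 1e-12


@dataclass
class PredictionEnsemble:
    """Trajectories of one prediction across one parameter's samples."""

    prediction: str
    param: str
    times: np.ndarray
    sample_trajectories: np.ndarray   # shape (n_samples, n_times)
    mle_trajectory: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.sample_trajectories = np.atleast_2d(
            np.asarray(self.sample_trajectories, dtype=float)
        )
        self.mle_trajectory = np.asarray(self.mle_trajectory, dtype=float)
        if self.sample_trajectories.shape[0] < 1:
            raise ValueError("ensemble needs at least one sample trajectory")
        if self.sample_trajectories.shape[1] != self.times.size:
            raise ValueError("sample trajectories do not match the time grid")


@dataclass
class PLSResult:
    """PLS indices of one prediction for all parameters."""

    prediction: str
    param_labels: tuple[str, ...]
    times: np.ndarray
    s: np.ndarray          # shape (n_theta, n_times)
    s_tilde: np.ndarray
    s_tot: float
    J_k: np.ndarray
    J_tot: float


def _extract_prediction(
    model: DynamicModel,
    traj,
    params: Log10ParameterVector,
    label: str,
) -> np.ndarray:
    if label in model.readouts:
        return evaluate_readout(model, traj, params, label)
    return traj.state(label)


def prediction_ensemble(
    model: DynamicModel,
    samples: ParameterSampleSet,
    design: ExperimentDesign,
    prediction: str,
    times: np.ndarray,
    theta_hat: Log10ParameterVector,
    rtol: float | None = None,
    atol: float | None = None,
) -> PredictionEnsemble:
    """Simulate every profile sample and the MLE; extract one prediction.

    Samples whose simulation fails are dropped with a warning; if all
    fail the ensemble cannot be built.
    """
    kwargs = {}
    if rtol is not None:
        kwargs["rtol"] = rtol
    if atol is not None:
        kwargs["atol"] = atol
    times = np.asarray(times, dtype=float)
    rows = []
    n_dropped = 0
    for pv in samples.samples:
        try:
            traj = simulate(model, pv, design, times, **kwargs)
            rows.append(_extract_prediction(model, traj, pv, prediction))
        except SimulationError:
            n_dropped += 1
    if n_dropped:
        warnings.warn(
            f"{n_dropped}/{len(samples)} profile samples of {samples.param} "
            f"failed to simulate and were dropped"
        )
    if not rows:
        raise SimulationError(
            f"every sample of {samples.param} failed for prediction {prediction}"
        )
    mle_traj = simulate(model, theta_hat, design, times, **kwargs)
    return PredictionEnsemble(
        prediction=prediction,
        param=samples.param,
        times=times,
        sample_trajectories=np.vstack(rows),
        mle_trajectory=_extract_prediction(model, mle_traj, theta_hat, prediction),
    )


def _time_average(times: np.ndarray, y: np.ndarray) -> float:
    """Trapezoidal time average; robust to non-uniform grids."""
    if times.size == 1:
        return float(y[0])
    return float(np.trapezoid(y, times) / (times[-1] - times[0]))


def pls_index(ens: PredictionEnsemble) -> np.ndarray:
    """s_i(t_k): squared ensemble spread over the MLE time average."""
    denom = _time_average(ens.times, ens.mle_trajectory)
    if abs(denom) < DEGENERATE_MEAN:
        raise ZeroDivisionError(
            f"MLE trajectory of {ens.prediction} has (near-)zero time average "
            f"({denom:g}); the PLS index is undefined for this prediction"
        )
    spread = ens.sample_trajectories.max(axis=0) - ens.sample_trajectories.min(axis=0)
    return (spread / denom) ** 2


def pls_total(s_matrices) -> float:
    """Sum of PLS indices over parameters and times."""
    mats = [np.atleast_1d(np.asarray(m, dtype=float)) for m in s_matrices]
    shape = mats[0].shape
    for m in mats[1:]:
        if m.shape != shape:
            raise ValueError("PLS matrices have mismatched shapes")
    return float(sum(m.sum() for m in mats))


def pls_entropy(s: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-time Shannon entropy of normalized PLS indices.

    Columns of ``s`` (times) are normalized to sum to one; 0*log(0) is
    taken as 0. Times at which no parameter contributes (zero column)
    get J_k = 0 and are logged.
    """
    s = np.atleast_2d(np.asarray(s, dtype=float))
    if np.any(s < 0):
        raise ValueError("PLS indices must be nonnegative")
    col = s.sum(axis=0)
    zero_cols = col <= 0
    if np.any(zero_cols):
        logger.info("pls_entropy: %d zero columns contribute J_k = 0", zero_cols.sum())
    safe = np.where(zero_cols, 1.0, col)
    s_tilde = s / safe
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(s_tilde > 0, -s_tilde * np.log(s_tilde), 0.0)
    J_k = term.sum(axis=0)
    J_k[zero_cols] = 0.0
    return J_k, float(J_k.sum())


def pls_summary(
    model: DynamicModel,
    sample_sets: dict[str, ParameterSampleSet],
    design: ExperimentDesign,
    theta_hat: Log10ParameterVector,
    predictions,
    times: np.ndarray,
    rtol: float | None = None,
    atol: float | None = None,
) -> dict[str, PLSResult]:
    """Assemble the full s matrix per prediction and both criteria.

    ``sample_sets`` must hold one ParameterSampleSet per model parameter;
    the result maps each prediction label to its PLSResult, whose
    (s_tot, J_tot) pair is that prediction's point in criterion space.
    """
    missing = [p for p in model.param_labels if p not in sample_sets]
    if missing:
        raise ValueError(f"no profile samples for parameters {missing}")
    times = np.asarray(times, dtype=float)
    out: dict[str, PLSResult] = {}
    for pred in predictions:
        rows = []
        for p in model.param_labels:
            ens = prediction_ensemble(
                model, sample_sets[p], design, pred, times, theta_hat,
                rtol=rtol, atol=atol,
            )
            rows.append(pls_index(ens))
        s = np.vstack(rows)
        J_k, J_tot = pls_entropy(s)
        col = s.sum(axis=0)
        s_tilde = s / np.where(col > 0, col, 1.0)
        out[pred] = PLSResult(
            prediction=pred,
            param_labels=model.param_labels,
            times=times,
            s=s,
            s_tilde=s_tilde,
            s_tot=float(s.sum()),
            J_k=J_k,
            J_tot=J_tot,
        )
    return out
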