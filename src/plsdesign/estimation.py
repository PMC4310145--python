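"""Residual objective, replicate normalization and multi-start MLE.

Under the additive Gaussian noise model eps ~ N(0, sigma_exp^2) the
weighted residual sum of squares

    chi2(theta) = sum_i (y_exp(t_i) - y_sim(t_i))^2 / sigma_exp(t_i)^2

is proportional to -2 log L, so its minimizer is the maximum-likelihood
estimate. Optimization runs in log10 parameter space with bounded
trust-region least squares; multi-start initial points come from a
Latin hypercube over the parameter box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model_core import (
    DynamicModel,
    ExperimentDesign,
    SimulationError,
    evaluate_readout,
    simulate,
)
from .parameters import Log10ParameterVector

__all__ = [
    "Dataset",
    "FitResult",
    "EstimationError",
    "AlignmentError",
    "chi_squared",
    "normalize_replicates",
    "fit_mle",
    "residual_function",
    "predict_dataset",
]

SIGMA_REL_FLOOR = 1e-3   # sigma floored at 1e-3 * max|y_exp| per readout
SIGMA_ABS_FLOOR = 1e-12

# residual magnitude standing in for an infinite objective when the ODE
# solver fails at a trial point (rejected step, not fatal)
_FAIL_RESIDUAL = 1e6


class EstimationError(RuntimeError):
    pass


class AlignmentError(ValueError):
    pass


@dataclass
class Dataset:
    """Observed time courses: one record per (time, readout).

    ``table`` columns: time, readout, mean, sd, n_rep.
    """

    table: pd.DataFrame
    provenance: str = "measured"

    REQUIRED = ("time", "readout", "mean", "sd", "n_rep")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise AlignmentError(f"dataset missing columns {missing}")
        t = self.table
        if (t["sd"] <= 0).any():
            raise ValueError("noise SD must be strictly positive everywhere")
        if (t["n_rep"] < 1).any():
            raise ValueError("replicate count must be >= 1")
        for lab, grp in t.groupby("readout", sort=False):
            if np.any(np.diff(grp["time"].to_numpy()) <= 0):
                raise ValueError(f"times for readout {lab!r} not strictly increasing")

    @classmethod
    def from_records(cls, times, readout, mean, sd, n_rep=1, provenance="measured"):
        df = pd.DataFrame(
            {
                "time": np.asarray(times, dtype=float),
                "readout": readout,
                "mean": np.asarray(mean, dtype=float),
                "sd": np.asarray(sd, dtype=float),
                "n_rep": n_rep,
            }
        )
        return cls(df, provenance)

    def readouts(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.table["readout"]))

    def for_readout(self, label: str) -> pd.DataFrame:
        return self.table[self.table["readout"] == label]

    def merge(self, other: "Dataset") -> "Dataset":
        df = pd.concat([self.table, other.table], ignore_index=True)
        prov = self.provenance if self.provenance == other.provenance else (
            f"{self.provenance}+{other.provenance}"
        )
        return Dataset(df, prov)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class FitResult:
    """Best-of-multi-start MLE with per-start diagnostics."""

    theta_hat: Log10ParameterVector
    chi2_min: float
    starts_table: list[dict] = field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "theta_hat": self.theta_hat.as_dict(),
            "chi2_min": self.chi2_min,
            "seed": self.seed,
            "starts": self.starts_table,
        }


def chi_squared(data: Dataset, predicted: dict[str, np.ndarray]) -> float:
    """Weighted residual sum of squares over all records.

    ``predicted`` maps each observed readout label to model values
    aligned with that readout's records (same order as the dataset).
    """
    total = 0.0
    for lab in data.readouts():
        grp = data.for_readout(lab)
        if lab not in predicted:
            raise AlignmentError(f"no prediction for readout {lab!r}")
        y_sim = np.asarray(predicted[lab], dtype=float)
        if y_sim.shape != (len(grp),):
            raise AlignmentError(
                f"prediction for {lab!r} has {y_sim.size} values, expected {len(grp)}"
            )
        res = (grp["mean"].to_numpy() - y_sim) / grp["sd"].to_numpy()
        total += float(np.dot(res, res))
    return total


def normalize_replicates(
    raw: pd.DataFrame, readout: str = "F", provenance: str = "measured"
) -> Dataset:
    """Normalize replicate traces to [0, 1] and pool them into a Dataset.

    Each replicate column is rescaled by its own ground value F0 = F(t=0)
    and maximum Fm:  Fn = (F - F0) / (Fm - F0).  The dataset mean and SD
    are the pointwise sample statistics across normalized replicates;
    SDs are floored (see SIGMA_REL_FLOOR) so coincident replicates do not
    produce infinite weights.
    """
    if "time" not in raw.columns or raw.shape[1] < 3:
        raise AlignmentError("raw replicate table needs `time` plus >= 2 replicates")
    times = raw["time"].to_numpy(dtype=float)
    reps = raw.drop(columns="time").to_numpy(dtype=float)
    normed = np.empty_like(reps)
    for j in range(reps.shape[1]):
        f0 = reps[0, j]
        fm = reps[:, j].max()
        if math.isclose(fm, f0):
            raise ValueError(f"degenerate replicate {j}: Fm == F0")
        normed[:, j] = (reps[:, j] - f0) / (fm - f0)
    mean = normed.mean(axis=1)
    sd = normed.std(axis=1, ddof=1)
    floor = max(SIGMA_REL_FLOOR * np.max(np.abs(mean)), SIGMA_ABS_FLOOR)
    sd = np.maximum(sd, floor)
    return Dataset.from_records(
        times, readout, mean, sd, n_rep=reps.shape[1], provenance=provenance
    )


def predict_dataset(
    model: DynamicModel,
    params: Log10ParameterVector,
    design: ExperimentDesign,
    data: Dataset,
    rtol: float | None = None,
    atol: float | None = None,
) -> dict[str, np.ndarray]:
    """Simulate once over the union of data times and align per readout."""
    kwargs = {}
    if rtol is not None:
        kwargs["rtol"] = rtol
    if atol is not None:
        kwargs["atol"] = atol
    all_times = np.unique(data.table["time"].to_numpy(dtype=float))
    traj = simulate(model, params, design, all_times, **kwargs)
    out = {}
    for lab in data.readouts():
        y = evaluate_readout(model, traj, params, lab)
        idx = np.searchsorted(all_times, data.for_readout(lab)["time"].to_numpy())
        out[lab] = y[idx]
    return out


def residual_function(
    model: DynamicModel,
    data: Dataset,
    design: ExperimentDesign,
    rtol: float | None = None,
    atol: float | None = None,
):
    """Build ``r(theta_array) -> weighted residual vector`` for least squares.

    Simulation failures return a large constant residual (infinite
    objective: the step is rejected, optimization continues).
    """
    labels = model.param_labels
    n_res = len(data)
    # precompute alignment once: union time grid + per-readout indices
    all_times = np.unique(data.table["time"].to_numpy(dtype=float))
    readout_list = data.readouts()
    idx, y_exp, sd = [], [], []
    for lab in readout_list:
        grp = data.for_readout(lab)
        idx.append(np.searchsorted(all_times, grp["time"].to_numpy(dtype=float)))
        y_exp.append(grp["mean"].to_numpy(dtype=float))
        sd.append(grp["sd"].to_numpy(dtype=float))
    y_exp = np.concatenate(y_exp)
    sd = np.concatenate(sd)
    kwargs = {}
    if rtol is not None:
        kwargs["rtol"] = rtol
    if atol is not None:
        kwargs["atol"] = atol

    def resid(theta: np.ndarray) -> np.ndarray:
        pv = Log10ParameterVector(labels, theta)
        try:
            traj = simulate(model, pv, design, all_times, **kwargs)
        except SimulationError:
            return np.full(n_res, _FAIL_RESIDUAL)
        y_sim = np.concatenate(
            [
                evaluate_readout(model, traj, pv, lab)[idx[i]]
                for i, lab in enumerate(readout_list)
            ]
        )
        return (y_sim - y_exp) / sd

    return resid


def fd_jacobian(resid, step: float = 1e-4):
    """Forward-difference jacobian with an *absolute* step in log10 space.

    scipy's built-in relative steps collapse for log10 parameters near
    zero and then sit below the ODE-solver truncation error, which turns
    the jacobian into noise; a fixed absolute step of ``step`` decades is
    both meaningful (a constant multiplicative perturbation) and safely
    above solver error.
    """

    def jac(x, f0=None):
        r0 = resid(x) if f0 is None else np.asarray(f0)
        J = np.empty((r0.size, x.size))
        for j in range(x.size):
            xp = x.copy()
            xp[j] += step
            J[:, j] = (resid(xp) - r0) / step
        return J

    return jac


def _lhs_starts(bounds_lo, bounds_hi, n, seed):
    sampler = qmc.LatinHypercube(d=len(bounds_lo), seed=seed)
    unit = sampler.random(n)
    return qmc.scale(unit, bounds_lo, bounds_hi)


def fit_mle(
    model: DynamicModel,
    data: Dataset,
    design: ExperimentDesign,
    start: Log10ParameterVector,
    n_starts: int = 20,
    seed: int = 0,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    bound_halfwidth: float = 3.0,
    ftol: float = 1e-8,
    xtol: float = 1e-8,
    max_nfev: int = 500,
    fd_step: float = 1e-4,
    rtol: float | None = None,
    atol: float | None = None,
) -> FitResult:
    """Multi-start bounded least squares on log10 parameters.

    The first start is the user-provided guess verbatim; the remaining
    ``n_starts - 1`` come from a Latin hypercube over the bounds box
    (default: +/- ``bound_halfwidth`` log10 units around the guess).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if bounds is None:
        lo = start.values - bound_halfwidth
        hi = start.values + bound_halfwidth
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    resid = residual_function(model, data, design, rtol=rtol, atol=atol)

    starts = [np.clip(start.values, lo, hi)]
    if n_starts > 1:
        starts.extend(_lhs_starts(lo, hi, n_starts - 1, seed))

    rows, best = [], None
    for k, x0 in enumerate(starts):
        try:
            sol = least_squares(
                resid, x0, jac=fd_jacobian(resid, fd_step),
                bounds=(lo, hi), method="trf",
                ftol=ftol, xtol=xtol, max_nfev=max_nfev,
            )
            chi2 = float(2 * sol.cost)
            # a start that exhausts its evaluation budget on a flat
            # objective still yields a valid (if unpolished) optimum;
            # only simulation blow-ups disqualify it
            ok = np.isfinite(chi2) and chi2 < _FAIL_RESIDUAL**2
        except Exception as exc:  # solver blow-up on a pathological start
            rows.append({"start": list(x0), "chi2": None, "converged": False,
                         "message": str(exc)})
            continue
        rows.append({"start": list(map(float, x0)), "chi2": chi2,
                     "converged": ok, "message": str(sol.message)})
        if ok and (best is None or chi2 < best[0]):
            best = (chi2, sol.x)
    if best is None:
        raise EstimationError(
            f"all {n_starts} starts failed; diagnostics: {rows}"
        )
    return FitResult(
        theta_hat=Log10ParameterVector(model.param_labels, best[1]),
        chi2_min=best[0],
        starts_table=rows,
        seed=seed,
    )
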