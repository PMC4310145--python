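"""ODE model class, stimulus, interventions and simulation.

The model class is

    dx/dt = f(x(t, theta_x), u(t), theta_x),     y(t) = g(x, theta_y) + eps

with states x, external stimulus u(t), kinetic parameters theta_x and
readout parameters theta_y collected into one vector theta. Initial
conditions may depend on the parameters (e.g. a pool size that is itself
estimated), so the model carries a callable ``initial_state`` that is
re-evaluated at every simulation.

Interventions emulate inhibitor experiments: the linear-scale value of a
targeted rate constant is multiplied by a small factor (default 1e-4)
before integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.integrate import odeint, solve_ivp

from .parameters import Log10ParameterVector

__all__ = [
    "ConfigurationError",
    "SimulationError",
    "DynamicModel",
    "StimulusProfile",
    "Intervention",
    "ExperimentDesign",
    "StateTrajectories",
    "simulate",
    "evaluate_readout",
    "apply_intervention",
]

DEFAULT_RTOL = 1e-7
DEFAULT_ATOL = 1e-9


class ConfigurationError(ValueError):
    """Invalid model / design configuration (unknown labels, bad fields)."""


class SimulationError(RuntimeError):
    """ODE integration failed; carries the offending parameter vector."""

    def __init__(self, message: str, params: Log10ParameterVector | None = None):
        super().__init__(message)
        self.params = params


@dataclass(frozen=True)
class StimulusProfile:
    """External light/input profile u(t): constant, or a rectangular pulse."""

    kind: str = "constant"  # "constant" | "pulse"
    amplitude: float = 0.0
    start: float = 0.0
    duration: float = float("inf")

    def __post_init__(self):
        if self.kind not in ("constant", "pulse"):
            raise ConfigurationError(f"unknown stimulus kind {self.kind!r}")
        if self.amplitude < 0:
            raise ConfigurationError("stimulus amplitude must be >= 0")
        if self.kind == "pulse" and not self.duration > 0:
            raise ConfigurationError("pulse duration must be > 0")

    def __call__(self, t: float) -> float:
        if self.kind == "constant":
            return self.amplitude
        if self.start <= t < self.start + self.duration:
            return self.amplitude
        return 0.0

    def switch_times(self) -> list[float]:
        """Interior discontinuities, used to split the integration span."""
        if self.kind == "constant":
            return []
        out = []
        if self.start > 0:
            out.append(self.start)
        if np.isfinite(self.duration):
            out.append(self.start + self.duration)
        return out


@dataclass(frozen=True)
class Intervention:
    """Multiplicative inhibition of one rate constant (linear scale)."""

    target_param: str
    factor: float = 1e-4

    def __post_init__(self):
        if not self.factor > 0:
            raise ConfigurationError("intervention factor must be > 0")


@dataclass(frozen=True)
class ExperimentDesign:
    """Observed readouts, interventions, stimulus and measurement times."""

    observed: tuple[str, ...]
    stimulus: StimulusProfile
    times: tuple[float, ...]
    interventions: tuple[Intervention, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "observed", tuple(self.observed))
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "interventions", tuple(self.interventions))
        if not self.observed:
            raise ConfigurationError("design must observe at least one readout")
        if len(set(self.observed)) != len(self.observed):
            raise ConfigurationError("duplicate readout labels in design")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("measurement times must be strictly increasing")

    def with_readouts(self, extra: tuple[str, ...]) -> "ExperimentDesign":
        return replace(self, observed=self.observed + tuple(extra))

    def with_interventions(self, extra: tuple[Intervention, ...]) -> "ExperimentDesign":
        return replace(self, interventions=self.interventions + tuple(extra))


@dataclass
class DynamicModel:
    """An ODE model with parameter-dependent initial state and readouts.

    ``rhs(t, x, p, u)`` receives the *linear-scale* parameter map ``p``;
    ``initial_state(p)`` likewise. Each readout is a callable
    ``(states, p) -> trajectory`` where ``states`` maps state label to a
    time-series array.
    """

    name: str
    state_labels: tuple[str, ...]
    param_labels: tuple[str, ...]
    rhs: Callable
    initial_state: Callable
    readouts: dict[str, Callable] = field(default_factory=dict)
    constants: dict[str, float] = field(default_factory=dict)
    # for linear mass-action networks dx/dt = M x + b u: callable
    # p -> (M, b); simulation then uses the closed-form matrix-exponential
    # solution instead of a numerical integrator
    linear_system: Callable | None = None
    # analytic jacobian of rhs w.r.t. the states, (t, x, p, u) -> (n, n);
    # passed to the stiff integrator when available
    rhs_jac: Callable | None = None
    # optional low-overhead ODE callbacks: (p, u) -> (f(y, t), jac(y, t))
    # in odeint argument order; used for hot-loop simulation of stiff
    # nonlinear models (e.g. a numba-compiled right-hand side)
    fast_ode: Callable | None = None

    def __post_init__(self):
        self.state_labels = tuple(self.state_labels)
        self.param_labels = tuple(self.param_labels)
        if not self.state_labels or not self.param_labels:
            raise ConfigurationError("state and parameter label lists must be non-empty")
        if len(set(self.state_labels)) != len(self.state_labels):
            raise ConfigurationError("duplicate state labels")
        if len(set(self.param_labels)) != len(self.param_labels):
            raise ConfigurationError("duplicate parameter labels")

    def params(self, mapping) -> Log10ParameterVector:
        """Build a log10 parameter vector in this model's canonical order."""
        missing = [k for k in self.param_labels if k not in mapping]
        if missing:
            raise ConfigurationError(f"missing parameters: {missing}")
        return Log10ParameterVector(self.param_labels, [mapping[k] for k in self.param_labels])


@dataclass
class StateTrajectories:
    """Simulation output: states evaluated on a time grid."""

    times: np.ndarray
    values: np.ndarray  # shape (n_states, n_times)
    state_labels: tuple[str, ...]
    params: Log10ParameterVector

    def state(self, label: str) -> np.ndarray:
        try:
            i = self.state_labels.index(label)
        except ValueError:
            raise ConfigurationError(f"unknown state {label!r}") from None
        return self.values[i]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {lab: self.values[i] for i, lab in enumerate(self.state_labels)}


def apply_intervention(
    params: Log10ParameterVector, iv: Intervention
) -> Log10ParameterVector:
    """Scale one parameter's linear value by ``iv.factor`` (copy returned)."""
    if iv.target_param not in params.labels:
        raise ConfigurationError(f"unknown intervention target {iv.target_param!r}")
    return params.with_value(
        iv.target_param, params[iv.target_param] + np.log10(iv.factor)
    )


def _effective_params(
    model: DynamicModel, params: Log10ParameterVector, design: ExperimentDesign
) -> Log10ParameterVector:
    for iv in design.interventions:
        if iv.target_param not in model.param_labels:
            raise ConfigurationError(f"unknown intervention target {iv.target_param!r}")
        params = apply_intervention(params, iv)
    return params


def simulate(
    model: DynamicModel,
    params: Log10ParameterVector,
    design: ExperimentDesign,
    eval_times: np.ndarray,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
) -> StateTrajectories:
    """Integrate the model at ``eval_times`` under the given design.

    Interventions are applied to the parameter vector first; the initial
    state is derived from the post-intervention parameters. The span is
    split at stimulus discontinuities so the stiff solver never steps
    across a jump in u(t).
    """
    eval_times = np.asarray(eval_times, dtype=float)
    if eval_times.ndim != 1 or eval_times.size == 0:
        raise ConfigurationError("eval_times must be a non-empty 1-d grid")
    if np.any(np.diff(eval_times) <= 0):
        raise ConfigurationError("eval_times must be strictly increasing")
    if tuple(params.labels) != tuple(model.param_labels):
        raise ConfigurationError("parameter vector does not match model labels")

    params_eff = _effective_params(model, params, design)
    p = params_eff.to_linear()
    x0 = np.asarray(model.initial_state(p), dtype=float)
    if x0.shape != (len(model.state_labels),) or not np.all(np.isfinite(x0)):
        raise SimulationError("initial_state returned an invalid vector", params_eff)

    t0 = min(0.0, eval_times[0])
    t_end = eval_times[-1]
    breaks = [t for t in design.stimulus.switch_times() if t0 < t < t_end]
    spans = list(zip([t0, *breaks], [*breaks, t_end]))

    if model.linear_system is not None:
        try:
            return _simulate_linear(model, params_eff, p, x0, design, eval_times, spans, t0)
        except np.linalg.LinAlgError:
            pass  # defective system matrix: fall through to the integrator

    out = np.empty((len(model.state_labels), eval_times.size))
    filled = 0
    if eval_times[0] == t0:
        out[:, 0] = x0
        filled = 1
    x = x0
    for a, b in spans:
        mask = (eval_times > a) & (eval_times <= b)
        t_req = eval_times[mask]
        # u(t) is constant inside each span (spans split at discontinuities)
        u_val = design.stimulus(0.5 * (a + b))
        if method == "LSODA":
            # lsoda via odeint: far lower per-step overhead than solve_ivp
            if model.fast_ode is not None:
                f, dfun = model.fast_ode(p, u_val)
            else:
                f = lambda y, t: model.rhs(t, y, p, u_val)
                dfun = None
                if model.rhs_jac is not None:
                    dfun = lambda y, t: model.rhs_jac(t, y, p, u_val)
            t_pts = np.concatenate([[a], t_req, [b]]) if (
                t_req.size == 0 or t_req[-1] < b
            ) else np.concatenate([[a], t_req])
            with np.errstate(all="ignore"):
                y, info = odeint(
                    f, x, t_pts, Dfun=dfun, rtol=rtol, atol=atol,
                    full_output=True, mxstep=100000,
                )
            if info["message"] != "Integration successful." or not np.all(
                np.isfinite(y)
            ):
                raise SimulationError(
                    f"integration failed on [{a:g}, {b:g}]: {info['message']}",
                    params_eff,
                )
            out[:, filled : filled + t_req.size] = y[1 : 1 + t_req.size].T
            filled += t_req.size
            x = y[-1]
        else:
            t_eval = t_req if t_req.size and t_req[-1] == b else np.append(t_req, b)
            jac = None
            if model.rhs_jac is not None:
                jac = lambda t, y: model.rhs_jac(t, y, p, u_val)
            sol = solve_ivp(
                lambda t, y: model.rhs(t, y, p, u_val),
                (a, b),
                x,
                method=method,
                t_eval=t_eval,
                rtol=rtol,
                atol=atol,
                jac=jac,
            )
            if not sol.success or not np.all(np.isfinite(sol.y)):
                raise SimulationError(
                    f"integration failed on [{a:g}, {b:g}]: {sol.message}", params_eff
                )
            out[:, filled : filled + t_req.size] = sol.y[:, : t_req.size]
            filled += t_req.size
            x = sol.y[:, -1]

    if not np.all(np.isfinite(out)):
        raise SimulationError("non-finite state values in solution", params_eff)
    return StateTrajectories(eval_times, out, model.state_labels, params_eff)


def _simulate_linear(model, params_eff, p, x0, design, eval_times, spans, t0):
    """Closed-form solution of dx/dt = M x + b u by eigendecomposition.

    Exact up to the conditioning of the eigenbasis; raises LinAlgError on
    a (near-)defective M so the caller can fall back to the integrator.
    """
    M, b = model.linear_system(p)
    M = np.asarray(M, dtype=float)
    b = np.asarray(b, dtype=float)
    lam, V = np.linalg.eig(M)
    if np.linalg.cond(V) > 1e10:
        raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
    Vinv = np.linalg.inv(V)
    out = np.empty((len(model.state_labels), eval_times.size))
    if eval_times[0] == t0:
        out[:, 0] = x0
    x = x0.astype(complex)
    for a, bnd in spans:
        mask = (eval_times > a) & (eval_times <= bnd)
        tau = np.append(eval_times[mask] - a, bnd - a)  # last entry: span end
        u_val = design.stimulus(0.5 * (a + bnd))
        w = Vinv @ x
        c = Vinv @ b.astype(complex)
        E = np.exp(np.outer(lam, tau))                   # (n, n_tau)
        with np.errstate(divide="ignore", invalid="ignore"):
            G = np.where(
                np.abs(lam)[:, None] > 1e-300,
                (E - 1.0) / lam[:, None],
                tau[None, :],
            )
        X = V @ (E * w[:, None]) + u_val * (V @ (G * c[:, None]))
        out[:, mask] = X[:, :-1].real
        x = X[:, -1]
    if not np.all(np.isfinite(out)):
        raise SimulationError("non-finite state values in solution", params_eff)
    return StateTrajectories(eval_times, out, model.state_labels, params_eff)


def evaluate_readout(
    model: DynamicModel,
    traj: StateTrajectories,
    params: Log10ParameterVector,
    label: str,
) -> np.ndarray:
    """Apply the readout map g pointwise along a simulated trajectory."""
    if label not in model.readouts:
        raise ConfigurationError(f"undefined readout {label!r}")
    return np.asarray(model.readouts[label](traj.as_dict(), params.to_linear()), dtype=float)
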