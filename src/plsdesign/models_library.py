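"""Bundled dynamic models.

Two models ship with the package:

``insilico4``
    A 4-species mass-action network (states A, B, C, D). A stimulus
    pulse u feeds A; two parallel routes activate the readout state D
    (A -> B -> D with rates k11, k12 and A <-> C -> D with rates k21,
    k22, k23) and D decays through a first-order sink d. The parallel
    routes compensate each other, which makes every rate constant
    practically non-identifiable when only D is measured — the model is
    a minimal testbed for readout/intervention selection.

``dsalina``
    A 5-state model of chlorophyll fluorescence induction in the green
    alga Dunaliella salina. States are probabilities/pool levels of
    excited antennae A* (x1), reduced first quinone acceptor Q_A^- (x2),
    singly and doubly reduced second acceptor Q_B^- (x3) and Q_B^2- (x4),
    and the plastoquinone pool PQ (x5). Light of intensity u excites
    antennae; excitation decays radiatively (k2, observed as
    fluorescence F = G*k2*x1) or drives electron transport through
    Q_A -> Q_B -> PQ. The antenna pool size A0 = 290 is fixed; the 13
    remaining parameters (k1..k10, PQ0, r2, G) are estimated.

Both models can also be exported/loaded as declarative YAML specs so
users can copy and modify them (see :func:`model_from_spec`).
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import yaml

from .model_core import ConfigurationError, DynamicModel
from .parameters import Log10ParameterVector

__all__ = [
    "build_insilico_model",
    "build_dsalina_model",
    "get_model",
    "model_from_spec",
    "INSILICO_TRUTH_LOG10",
    "DSALINA_MLE_LOG10",
]

# Ground-truth / reference parameter values on the log10 scale used for
# the bundled fixtures (in silico: fixture truth; D. salina: the
# fluorescence-data MLE used to generate synthetic induction curves).
INSILICO_TRUTH_LOG10 = {
    "k11": 0.043,
    "k12": 0.301,
    "k21": 0.398,
    "k22": 0.004,
    "k23": -0.301,
    "d": 0.004,
}

DSALINA_MLE_LOG10 = {
    "k1": -1.9507,
    "k2": 1.2603,
    "k3": 3.3192,
    "k4": 2.0231,
    "k5": 4.5278,
    "k6": 5.5047,
    "k7": 4.6765,
    "k8": 2.8452,
    "k9": 1.5753,
    "k10": 0.1611,
    "PQ0": 1.4930,
    "r2": -0.3069,
    "G": -2.8061,
}


def _insilico_rhs(t, x, p, u):
    A, B, C, D = x
    return np.array(
        [
            u - (p["k11"] + p["k21"]) * A + p["k22"] * C,
            p["k11"] * A - p["k12"] * B,
            p["k21"] * A - p["k22"] * C - p["k23"] * C,
            p["k12"] * B + p["k23"] * C - p["d"] * D,
        ]
    )


def _insilico_linear_system(p):
    M = np.array(
        [
            [-(p["k11"] + p["k21"]), 0.0, p["k22"], 0.0],
            [p["k11"], -p["k12"], 0.0, 0.0],
            [p["k21"], 0.0, -(p["k22"] + p["k23"]), 0.0],
            [0.0, p["k12"], p["k23"], -p["d"]],
        ]
    )
    return M, np.array([1.0, 0.0, 0.0, 0.0])


def build_insilico_model() -> DynamicModel:
    """The 4-species mass-action network with identity readouts A..D."""
    return DynamicModel(
        name="insilico4",
        state_labels=("A", "B", "C", "D"),
        param_labels=("k11", "k12", "k21", "k22", "k23", "d"),
        rhs=_insilico_rhs,
        initial_state=lambda p: np.zeros(4),
        readouts={
            "A": lambda s, p: s["A"],
            "B": lambda s, p: s["B"],
            "C": lambda s, p: s["C"],
            "D": lambda s, p: s["D"],
        },
        constants={},
        linear_system=_insilico_linear_system,
    )


A0 = 290.0  # antennae per antenna complex; fixed, not estimated


def _dsalina_rhs(t, x, p, u):
    x1, x2, x3, x4, x5 = x
    k1, k2, k3, k4 = p["k1"], p["k2"], p["k3"], p["k4"]
    k5, k6, k7, k8 = p["k5"], p["k6"], p["k7"], p["k8"]
    k9, k10 = p["k9"], p["k10"]
    r2 = p["r2"]
    exc = k1 * u * (A0 - x1)
    qa_fwd = k3 * x1 * (1.0 - x2)
    qa_back = k4 * x2 * (A0 - x1)
    qb_fwd = k5 * x2 * (r2 - x3 - x4)
    qb_back = k6 * x3 * (1.0 - x2)
    # second electron transfer Q_A^- + Q_B^- -> Q_B^2-; the back reaction
    # (k8) returns Q_B^2- to Q_B^- while re-reducing Q_A
    qb2_fwd = k7 * x2 * x3
    qb2_back = k8 * x4 * (1.0 - x2)
    pq_ox = k9 * x4 * x5
    return np.array(
        [
            exc - k2 * x1 - qa_fwd + qa_back,
            qa_fwd - qa_back - qb_fwd + qb_back - qb2_fwd + qb2_back,
            qb_fwd - qb_back - qb2_fwd + qb2_back,
            qb2_fwd - qb2_back - pq_ox,
            -pq_ox + p["k10"] * (p["PQ0"] - x5),
        ]
    )


def _dsalina_rhs_jac(t, x, p, u):
    x1, x2, x3, x4, x5 = x
    k1, k2, k3, k4 = p["k1"], p["k2"], p["k3"], p["k4"]
    k5, k6, k7, k8 = p["k5"], p["k6"], p["k7"], p["k8"]
    k9, k10 = p["k9"], p["k10"]
    r2 = p["r2"]
    J = np.zeros((5, 5))
    J[0, 0] = -k1 * u - k2 - k3 * (1 - x2) - k4 * x2
    J[0, 1] = k3 * x1 + k4 * (A0 - x1)
    J[1, 0] = k3 * (1 - x2) + k4 * x2
    J[1, 1] = -k3 * x1 - k4 * (A0 - x1) - k5 * (r2 - x3 - x4) - k6 * x3 - k7 * x3 - k8 * x4
    J[1, 2] = k5 * x2 + k6 * (1 - x2) - k7 * x2
    J[1, 3] = k5 * x2 + k8 * (1 - x2)
    J[2, 1] = k5 * (r2 - x3 - x4) + k6 * x3 - k7 * x3 - k8 * x4
    J[2, 2] = -k5 * x2 - k6 * (1 - x2) - k7 * x2
    J[2, 3] = -k5 * x2 + k8 * (1 - x2)
    J[3, 1] = k7 * x3 + k8 * x4
    J[3, 2] = k7 * x2
    J[3, 3] = -k8 * (1 - x2) - k9 * x5
    J[3, 4] = -k9 * x4
    J[4, 3] = -k9 * x5
    J[4, 4] = -k9 * x4 - k10
    return J


try:  # compiled hot path for the stiff induction model
    from numba import njit as _njit

    @_njit(cache=False)
    def _dsalina_f_nb(y, th, u):
        x1, x2, x3, x4, x5 = y[0], y[1], y[2], y[3], y[4]
        k1, k2, k3, k4, k5, k6, k7, k8, k9, k10, PQ0, r2 = (
            th[0], th[1], th[2], th[3], th[4], th[5], th[6], th[7], th[8],
            th[9], th[10], th[11],
        )
        exc = k1 * u * (290.0 - x1)
        qa_fwd = k3 * x1 * (1.0 - x2)
        qa_back = k4 * x2 * (290.0 - x1)
        qb_fwd = k5 * x2 * (r2 - x3 - x4)
        qb_back = k6 * x3 * (1.0 - x2)
        qb2_fwd = k7 * x2 * x3
        qb2_back = k8 * x4 * (1.0 - x2)
        pq_ox = k9 * x4 * x5
        out = np.empty(5)
        out[0] = exc - k2 * x1 - qa_fwd + qa_back
        out[1] = qa_fwd - qa_back - qb_fwd + qb_back - qb2_fwd + qb2_back
        out[2] = qb_fwd - qb_back - qb2_fwd + qb2_back
        out[3] = qb2_fwd - qb2_back - pq_ox
        out[4] = -pq_ox + k10 * (PQ0 - x5)
        return out

    @_njit(cache=False)
    def _dsalina_j_nb(y, th, u):
        x1, x2, x3, x4, x5 = y[0], y[1], y[2], y[3], y[4]
        k1, k2, k3, k4, k5, k6, k7, k8, k9, k10, PQ0, r2 = (
            th[0], th[1], th[2], th[3], th[4], th[5], th[6], th[7], th[8],
            th[9], th[10], th[11],
        )
        J = np.zeros((5, 5))
        J[0, 0] = -k1 * u - k2 - k3 * (1 - x2) - k4 * x2
        J[0, 1] = k3 * x1 + k4 * (290.0 - x1)
        J[1, 0] = k3 * (1 - x2) + k4 * x2
        J[1, 1] = (-k3 * x1 - k4 * (290.0 - x1) - k5 * (r2 - x3 - x4)
                   - k6 * x3 - k7 * x3 - k8 * x4)
        J[1, 2] = k5 * x2 + k6 * (1 - x2) - k7 * x2
        J[1, 3] = k5 * x2 + k8 * (1 - x2)
        J[2, 1] = k5 * (r2 - x3 - x4) + k6 * x3 - k7 * x3 - k8 * x4
        J[2, 2] = -k5 * x2 - k6 * (1 - x2) - k7 * x2
        J[2, 3] = -k5 * x2 + k8 * (1 - x2)
        J[3, 1] = k7 * x3 + k8 * x4
        J[3, 2] = k7 * x2
        J[3, 3] = -k8 * (1 - x2) - k9 * x5
        J[3, 4] = -k9 * x4
        J[4, 3] = -k9 * x5
        J[4, 4] = -k9 * x4 - k10
        return J

    def _dsalina_fast_ode(p, u):
        th = np.array(
            [p["k1"], p["k2"], p["k3"], p["k4"], p["k5"], p["k6"], p["k7"],
             p["k8"], p["k9"], p["k10"], p["PQ0"], p["r2"]]
        )
        return (lambda y, t: _dsalina_f_nb(y, th, u),
                lambda y, t: _dsalina_j_nb(y, th, u))

except ImportError:  # pure-python fallback, same contract
    def _dsalina_fast_ode(p, u):
        return (lambda y, t: _dsalina_rhs(t, y, p, u),
                lambda y, t: _dsalina_rhs_jac(t, y, p, u))


def build_dsalina_model() -> DynamicModel:
    """5-state chlorophyll fluorescence induction model for D. salina.

    Readouts: ``F`` (normalized fluorescence, F = G*k2*x1) plus the
    internal states ``x3`` (Q_B^-) and ``x5`` (PQ) exposed for design
    studies, and ``x1``..``x4`` for completeness.
    """
    readouts: dict[str, Callable] = {
        "F": lambda s, p: p["G"] * p["k2"] * s["x1"],
    }
    for lab in ("x1", "x2", "x3", "x4", "x5"):
        readouts[lab] = (lambda L: lambda s, p: s[L])(lab)
    return DynamicModel(
        name="dsalina",
        state_labels=("x1", "x2", "x3", "x4", "x5"),
        param_labels=(
            "k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9", "k10",
            "PQ0", "r2", "G",
        ),
        rhs=_dsalina_rhs,
        rhs_jac=_dsalina_rhs_jac,
        fast_ode=_dsalina_fast_ode,
        initial_state=lambda p: np.array([0.0, 0.0, 0.0, 0.0, p["PQ0"]]),
        readouts=readouts,
        constants={"A0": A0},
    )


_REGISTRY = {
    "insilico4": build_insilico_model,
    "dsalina": build_dsalina_model,
}


def get_model(name: str) -> DynamicModel:
    if name not in _REGISTRY:
        raise ConfigurationError(
            f"unknown model {name!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name]()


# ---------------------------------------------------------------------------
# Declarative model specs (YAML/JSON) for user-supplied models
# ---------------------------------------------------------------------------

_SAFE_FUNCS = {"exp": np.exp, "log": np.log, "sqrt": np.sqrt, "abs": np.abs}


def _compile_expr(expr: str, state_labels, param_labels, constants):
    """Compile a rate/readout expression into a callable over (x, p, u)."""
    code = compile(expr, "<model-spec>", "eval")
    for name in code.co_names:
        if name not in (*state_labels, *param_labels, *constants, "u", "t", *_SAFE_FUNCS):
            raise ConfigurationError(f"unknown symbol {name!r} in expression {expr!r}")

    def fn(t, x, p, u):
        env = dict(zip(state_labels, x))
        env.update(p)
        env.update(constants)
        env.update(_SAFE_FUNCS)
        env["u"] = u
        env["t"] = t
        return eval(code, {"__builtins__": {}}, env)

    return fn


def model_from_spec(spec: dict | str) -> DynamicModel:
    """Build a DynamicModel from a declarative spec (dict or YAML text).

    Schema::

        name: mymodel
        states: [A, B]
        parameters: [k1, k2]
        constants: {c: 1.0}
        odes:            # one expression per state, same order
          A: "u - k1*A"
          B: "k1*A - k2*B"
        initial: ["0", "0"]          # expressions over parameters/constants
        readouts: {y: "B"}
    """
    if isinstance(spec, str):
        spec = yaml.safe_load(spec)
    states = tuple(spec["states"])
    params = tuple(spec["parameters"])
    constants = dict(spec.get("constants", {}))
    ode_exprs = [
        _compile_expr(spec["odes"][s], states, params, constants) for s in states
    ]
    init_exprs = [
        _compile_expr(str(e), (), params, constants) for e in spec.get("initial", ["0"] * len(states))
    ]
    readout_fns = {}
    for lab, expr in spec.get("readouts", {}).items():
        fn = _compile_expr(expr, states, params, constants)

        def ro(s, p, _fn=fn, _states=states):
            n = len(next(iter(s.values())))
            x = np.array([s[lab_] for lab_ in _states])
            return np.array([_fn(0.0, x[:, j], p, 0.0) for j in range(n)])

        readout_fns[lab] = ro

    def rhs(t, x, p, u):
        return np.array([f(t, x, p, u) for f in ode_exprs])

    def initial(p):
        return np.array([f(0.0, (), p, 0.0) for f in init_exprs], dtype=float)

    return DynamicModel(
        name=str(spec.get("name", "user-model")),
        state_labels=states,
        param_labels=params,
        rhs=rhs,
        initial_state=initial,
        readouts=readout_fns,
        constants=constants,
    )


def model_to_spec(model_name: str) -> str:
    """YAML spec text for a bundled model (template for user edits)."""
    if model_name == "insilico4":
        spec = {
            "name": "insilico4",
            "states": ["A", "B", "C", "D"],
            "parameters": ["k11", "k12", "k21", "k22", "k23", "d"],
            "odes": {
                "A": "u - (k11 + k21)*A + k22*C",
                "B": "k11*A - k12*B",
                "C": "k21*A - k22*C - k23*C",
                "D": "k12*B + k23*C - d*D",
            },
            "initial": ["0", "0", "0", "0"],
            "readouts": {"A": "A", "B": "B", "C": "C", "D": "D"},
        }
    elif model_name == "dsalina":
        spec = {
            "name": "dsalina",
            "states": ["x1", "x2", "x3", "x4", "x5"],
            "parameters": [
                "k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9", "k10",
                "PQ0", "r2", "G",
            ],
            "constants": {"A0": A0},
            "odes": {
                "x1": "k1*u*(A0 - x1) - k2*x1 - k3*x1*(1 - x2) + k4*x2*(A0 - x1)",
                "x2": "k3*x1*(1 - x2) - k4*x2*(A0 - x1) - k5*x2*(r2 - x3 - x4)"
                      " + k6*x3*(1 - x2) - k7*x2*x3 + k8*x4*(1 - x2)",
                "x3": "k5*x2*(r2 - x3 - x4) - k6*x3*(1 - x2) - k7*x2*x3 + k8*x4*(1 - x2)",
                "x4": "k7*x2*x3 - k8*x4*(1 - x2) - k9*x4*x5",
                "x5": "-k9*x4*x5 + k10*(PQ0 - x5)",
            },
            "initial": ["0", "0", "0", "0", "PQ0"],
            "readouts": {"F": "G*k2*x1", "x3": "x3", "x5": "x5"},
        }
    else:
        raise ConfigurationError(f"unknown model {model_name!r}")
    return yaml.safe_dump(spec, sort_keys=False)


def reference_params(model_name: str) -> Log10ParameterVector:
    """Bundled log10 reference parameter vector for a registered model."""
    if model_name == "insilico4":
        return get_model("insilico4").params(INSILICO_TRUTH_LOG10)
    if model_name == "dsalina":
        return get_model("dsalina").params(DSALINA_MLE_LOG10)
    raise ConfigurationError(f"no reference parameters for {model_name!r}")
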