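"""Reproducible synthetic datasets and bundled study fixtures.

Observations are the simulated readout plus i.i.d. additive Gaussian
noise with a per-readout standard deviation

    sigma = max(sd_rel * <|y|>_t, sd_abs),

i.e. a fraction of the time-averaged signal magnitude with an absolute
floor. The recorded sigma is this generating value, so the weighting in
the residual objective is exactly the noise model that produced the
data.

Fixtures bundle the study scenarios end to end (model, design, dataset,
ground truth) as pure functions of their name and the packaged master
seed, so every pipeline stage can run without external downloads:

``insilico_baseline``     4-species network, only D observed.
``insilico_full_readout`` same network, all four states observed.
``dsalina_baseline``      fluorescence-only induction data at the
                          reference MLE, 200 log-spaced times on
                          [1e-4, 1] s, noise SD 1e-3 (normalized scale).
``dsalina_augmented``     baseline plus an in-silico Q_B^- (x3) readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import Dataset
from .model_core import (
    DynamicModel,
    ExperimentDesign,
    StimulusProfile,
    evaluate_readout,
    simulate,
)
from .models_library import get_model, reference_params
from .parameters import Log10ParameterVector

__all__ = ["NoiseSpec", "generate_dataset", "make_fixture", "Fixture", "MASTER_SEED"]

MASTER_SEED = 436  # packaged master seed; all fixture noise derives from it


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian observation noise, relative with absolute floor."""

    sd_rel: float = 0.05
    sd_abs: float = 1e-3
    allow_exact: bool = False  # permit sd_rel = sd_abs = 0 (noise-free data)

    def __post_init__(self):
        if self.sd_rel < 0 or self.sd_abs < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.sd_rel == 0 and self.sd_abs == 0 and not self.allow_exact:
            raise ValueError("zero noise requires allow_exact=True")

    def sigma(self, y: np.ndarray, times: np.ndarray) -> float:
        if times.size > 1:
            avg = np.trapezoid(np.abs(y), times) / (times[-1] - times[0])
        else:
            avg = abs(float(y[0]))
        return max(self.sd_rel * avg, self.sd_abs)


def generate_dataset(
    model: DynamicModel,
    params: Log10ParameterVector,
    design: ExperimentDesign,
    times: np.ndarray,
    noise: NoiseSpec,
    seed: int,
    n_rep: int = 1,
) -> Dataset:
    """Simulate the design and add per-readout Gaussian noise.

    The recorded per-point SD equals the generating sigma. With
    ``n_rep > 1`` the stored mean is the average of n_rep independent
    draws and the stored SD is sigma / sqrt(n_rep).
    """
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    traj = simulate(model, params, design, times)
    frames = []
    for lab in design.observed:
        y = evaluate_readout(model, traj, params, lab)
        sig = noise.sigma(y, times)
        if sig > 0:
            draws = y + rng.normal(0.0, sig, size=(n_rep, times.size))
            mean = draws.mean(axis=0)
            sd = sig / np.sqrt(n_rep)
        else:
            mean = y.copy()
            sd = 1.0  # exact data: unit weights keep chi2 well defined
        frames.append(
            Dataset.from_records(
                times, lab, mean, np.full(times.size, sd), n_rep=n_rep,
                provenance=f"synthetic:{seed}",
            ).table
        )
    return Dataset(pd.concat(frames, ignore_index=True), provenance=f"synthetic:{seed}")


@dataclass
class Fixture:
    """A fully specified, seeded study scenario."""

    name: str
    model: DynamicModel
    design: ExperimentDesign
    data: Dataset
    truth: Log10ParameterVector
    noise: NoiseSpec
    seed: int


# fixture condition constants
INSILICO_TIMES = np.linspace(0.0, 2.5, 16)
INSILICO_NOISE = NoiseSpec(sd_rel=0.10, sd_abs=0.01)
DSALINA_TIMES = np.logspace(-4, 0, 200)
# normalized-fluorescence noise: SD 1e-3 on the normalized scale, i.e. the
# precision of a replicate-averaged PAM trace; large enough to keep the PQ
# replenishment rate k10 unbounded below, small enough that the readout
# gain/pool parameters stay identifiable
DSALINA_NOISE = NoiseSpec(sd_rel=0.0, sd_abs=1e-3)
DSALINA_STIMULUS = StimulusProfile(kind="pulse", amplitude=166.0, start=0.0, duration=1.0)
# unit pulse: the network relaxes after stimulation, so the terminal state D
# plateaus and its degradation rate is only bounded from above by the data
INSILICO_STIMULUS = StimulusProfile(kind="pulse", amplitude=1.0, start=0.0, duration=1.0)


def _insilico_fixture(observed: tuple[str, ...], name: str, seed_offset: int) -> Fixture:
    model = get_model("insilico4")
    truth = reference_params("insilico4")
    design = ExperimentDesign(
        observed=observed, stimulus=INSILICO_STIMULUS, times=tuple(INSILICO_TIMES)
    )
    seed = MASTER_SEED + seed_offset
    data = generate_dataset(model, truth, design, INSILICO_TIMES, INSILICO_NOISE, seed)
    return Fixture(name, model, design, data, truth, INSILICO_NOISE, seed)


# noise for the augmented fixture's in-silico internal-state readout:
# relative to the channel's own scale (x3 lives at ~1e-2 while F is O(1));
# 2% of the time-averaged signal is the precision at which the added
# quinone readout actually constrains the plastoquinone replenishment rate
AUGMENTED_READOUT_NOISE = NoiseSpec(sd_rel=0.02, sd_abs=1e-4)


def _dsalina_fixture(observed: tuple[str, ...], name: str, seed_offset: int) -> Fixture:
    model = get_model("dsalina")
    truth = reference_params("dsalina")
    design = ExperimentDesign(
        observed=observed, stimulus=DSALINA_STIMULUS, times=tuple(DSALINA_TIMES)
    )
    seed = MASTER_SEED + seed_offset
    fluor_design = ExperimentDesign(
        observed=("F",), stimulus=DSALINA_STIMULUS, times=tuple(DSALINA_TIMES)
    )
    data = generate_dataset(model, truth, fluor_design, DSALINA_TIMES, DSALINA_NOISE, seed)
    extra = tuple(lab for lab in observed if lab != "F")
    if extra:
        aug_design = ExperimentDesign(
            observed=extra, stimulus=DSALINA_STIMULUS, times=tuple(DSALINA_TIMES)
        )
        data = data.merge(
            generate_dataset(
                model, truth, aug_design, DSALINA_TIMES, AUGMENTED_READOUT_NOISE, seed + 100
            )
        )
    return Fixture(name, model, design, data, truth, DSALINA_NOISE, seed)


def make_fixture(name: str) -> Fixture:
    """Build a bundled scenario; deterministic given the name."""
    if name == "insilico_baseline":
        return _insilico_fixture(("D",), name, 1)
    if name == "insilico_full_readout":
        return _insilico_fixture(("A", "B", "C", "D"), name, 2)
    if name == "dsalina_baseline":
        return _dsalina_fixture(("F",), name, 3)
    if name == "dsalina_augmented":
        return _dsalina_fixture(("F", "x3"), name, 4)
    raise KeyError(f"unknown fixture {name!r}")
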