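"""Serialization: dataset CSV, design YAML, profile/PLS CSV, JSON bundles.

CSV dialect: comma-separated, header row, ``.`` decimal, UTF-8.
JSON is written with sorted keys so re-runs diff cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimation import AlignmentError, Dataset, FitResult
from .model_core import ExperimentDesign, Intervention, StimulusProfile
from .parameters import Log10ParameterVector
from .pls import PLSResult
from .profiling import ConfidenceInterval, ProfileCurve

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_design",
    "write_design",
    "write_profile_csv",
    "read_profile_csv",
    "write_fit_json",
    "read_fit_json",
    "write_pls_result",
    "write_intervals_json",
    "write_criterion_csv",
]

DATASET_COLUMNS = ("time", "readout", "mean", "sd", "n_rep")


def read_dataset(path) -> Dataset:
    """Read a dataset CSV (``time,readout,mean,sd,n_rep``)."""
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise AlignmentError(f"{path}: missing columns {missing}")
    for col in ("time", "mean", "sd"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise AlignmentError(
                f"{path}: non-numeric value in column {col!r}, row {bad.index[0]}"
            )
        df[col] = pd.to_numeric(df[col])
    return Dataset(df[list(DATASET_COLUMNS)].copy())


def write_dataset(data: Dataset, path) -> None:
    data.table.to_csv(path, index=False)


def read_design(path) -> ExperimentDesign:
    """Read an experiment design from YAML/JSON."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return design_from_dict(doc)


def design_from_dict(doc: dict) -> ExperimentDesign:
    stim = doc.get("stimulus", {})
    return ExperimentDesign(
        observed=tuple(doc["observed"]),
        stimulus=StimulusProfile(
            kind=stim.get("kind", "constant"),
            amplitude=float(stim.get("amplitude", 0.0)),
            start=float(stim.get("start", 0.0)),
            duration=float(stim.get("duration", float("inf"))),
        ),
        times=tuple(float(t) for t in doc["times"]),
        interventions=tuple(
            Intervention(iv["target_param"], float(iv.get("factor", 1e-4)))
            for iv in doc.get("interventions", [])
        ),
    )


def design_to_dict(design: ExperimentDesign) -> dict:
    return {
        "observed": list(design.observed),
        "stimulus": {
            "kind": design.stimulus.kind,
            "amplitude": design.stimulus.amplitude,
            "start": design.stimulus.start,
            "duration": design.stimulus.duration,
        },
        "times": list(design.times),
        "interventions": [
            {"target_param": iv.target_param, "factor": iv.factor}
            for iv in design.interventions
        ],
    }


def write_design(design: ExperimentDesign, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False)


def write_profile_csv(curve: ProfileCurve, path) -> None:
    """Profile curve as CSV: grid, chi2_PL, convergence + nuisance vectors."""
    df = pd.DataFrame(
        {
            "param": curve.param,
            "grid_log10": curve.grid,
            "chi2_pl": curve.chi2_pl,
            "converged": curve.converged.astype(int),
        }
    )
    for j, lab in enumerate(curve.labels):
        df[f"nuisance_{lab}"] = curve.nuisance[:, j]
    df.to_csv(path, index=False)


def read_profile_csv(path) -> ProfileCurve:
    df = pd.read_csv(path)
    labels = tuple(c[len("nuisance_"):] for c in df.columns if c.startswith("nuisance_"))
    nuis = df[[f"nuisance_{lab}" for lab in labels]].to_numpy()
    param = str(df["param"].iloc[0])
    chi2 = df["chi2_pl"].to_numpy()
    grid = df["grid_log10"].to_numpy()
    j = int(np.argmin(chi2))
    return ProfileCurve(
        param=param,
        labels=labels,
        grid=grid,
        chi2_pl=chi2,
        nuisance=nuis,
        converged=df["converged"].to_numpy().astype(bool),
        chi2_min=float(chi2[j]),
        theta_hat_value=float(grid[j]),
    )


def write_fit_json(fit: FitResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fit.to_dict(), fh, sort_keys=True, indent=1)


def read_fit_json(path) -> FitResult:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return FitResult(
        theta_hat=Log10ParameterVector.from_mapping(doc["theta_hat"]),
        chi2_min=float(doc["chi2_min"]),
        starts_table=doc.get("starts", []),
        seed=doc.get("seed"),
    )


def write_pls_result(res: PLSResult, directory, stem: str) -> None:
    """PLS matrices as param x time CSV plus a JSON summary."""
    directory = Path(directory)
    s_df = pd.DataFrame(res.s, index=list(res.param_labels), columns=res.times)
    s_df.to_csv(directory / f"{stem}_s.csv", index_label="param")
    with open(directory / f"{stem}_summary.json", "w", encoding="utf-8") as fh:
        json.dump(
            {"prediction": res.prediction, "s_tot": res.s_tot, "J_tot": res.J_tot},
            fh, sort_keys=True, indent=1,
        )


def write_intervals_json(intervals: dict[str, ConfidenceInterval], path) -> None:
    doc = {
        p: {
            "lower": None if not np.isfinite(ci.lower) else ci.lower,
            "upper": None if not np.isfinite(ci.upper) else ci.upper,
            "alpha": ci.alpha,
            "df": ci.df,
            "identifiability": ci.identifiability,
        }
        for p, ci in intervals.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)


def write_criterion_csv(points, path) -> None:
    pd.DataFrame(
        [
            {"id": p.candidate_id, "s_tot": p.s_tot, "J_tot": p.J_tot,
             "pareto": int(p.pareto)}
            for p in points
        ]
    ).to_csv(path, index=False)
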