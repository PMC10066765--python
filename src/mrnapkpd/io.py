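"""Dataset files, run configuration and manifests.

Datasets are CSV in NONMEM column conventions (ID, TIME, EVID, AMT, RATE,
DV, DVID, MDV, BLQ, LLOQ, WT, SPECIES; "." for missing) so they
interoperate with standard pharmacometrics tooling.  Reading validates the
record-level invariants and reports violations with line numbers; writing
is canonical, so read → write → read is lossless and a second write is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas
import yaml
from pydantic import BaseModel, ConfigDict

from .estimation import FitResult
from .population import DATASET_COLUMNS, OBSERVABLES

__all__ = [
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "RunConfig",
    "load_config",
    "fit_result_to_dict",
    "write_fit_result",
    "write_manifest",
]

_NUM_COLS = ["TIME", "EVID", "AMT", "RATE", "DV", "MDV", "BLQ", "LLOQ", "WT"]
_INT_COLS = ["EVID", "MDV", "BLQ"]


class DatasetError(ValueError):
    """A dataset contract violation, annotated with the offending line."""


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        if np.isnan(value):
            return "."
        if value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return repr(float(value))
    return str(value)


def write_dataset(dataset: pandas.DataFrame, path) -> None:
    """Write a dataset in the canonical CSV dialect ("." for missing)."""
    path = Path(path)
    lines = [",".join(DATASET_COLUMNS)]
    for rec in dataset[DATASET_COLUMNS].itertuples(index=False):
        lines.append(",".join(_fmt(v) for v in rec))
    path.write_text("\n".join(lines) + "\n")


def read_dataset(path) -> pandas.DataFrame:
    """Read and validate a dataset CSV; raises :class:`DatasetError` with
    the line number on any contract violation."""
    path = Path(path)
    df = pandas.read_csv(
        path,
        na_values=["."],
        keep_default_na=False,
        dtype={"ID": str, "DVID": str, "SPECIES": str},
        float_precision="round_trip",
    )
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: missing required columns {missing}")
    for c in _NUM_COLS:
        df[c] = pandas.to_numeric(df[c], errors="coerce")
    df["DVID"] = df["DVID"].replace({"": "."}).fillna(".")
    validate_dataset(df, source=str(path))
    for c in _INT_COLS:
        df[c] = df[c].astype(int)
    return df[DATASET_COLUMNS]


def validate_dataset(df: pandas.DataFrame, source: str = "<memory>") -> None:
    """Enforce the record-level invariants of the long-format dataset."""

    def fail(i: int, msg: str):
        # +2: header line plus 1-based indexing
        raise DatasetError(f"{source}, line {i + 2}: {msg}")

    for i, r in enumerate(df.itertuples(index=False)):
        evid = r.EVID
        if evid not in (0, 1):
            fail(i, f"EVID must be 0 or 1, got {evid!r}")
        if np.isnan(r.TIME) or r.TIME < 0:
            fail(i, "TIME must be a non-negative number")
        if np.isnan(r.WT) or r.WT <= 0:
            fail(i, "WT must be a positive number")
        if evid == 1:
            if r.MDV != 1:
                fail(i, "dose records must have MDV=1")
            if not np.isnan(r.DV):
                fail(i, "dose records must have DV missing ('.')")
            if np.isnan(r.AMT) or r.AMT <= 0:
                fail(i, "dose records must have AMT > 0")
        else:
            if r.DVID not in OBSERVABLES:
                fail(i, f"DVID {r.DVID!r} not in {OBSERVABLES}")
            if r.MDV == 0 and np.isnan(r.DV):
                fail(i, "observation with MDV=0 must carry a DV value")
            if r.BLQ == 1:
                if np.isnan(r.LLOQ):
                    fail(i, "BLQ=1 requires a LLOQ value")
                if r.MDV != 0:
                    fail(i, "BLQ=1 records must have MDV=0")
                if not np.isclose(r.DV, r.LLOQ):
                    fail(i, "BLQ=1 records must carry DV equal to the LLOQ")
    # times sorted within subject
    for sid, grp in df.groupby("ID", sort=False):
        t = grp["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise DatasetError(f"{source}: times not sorted for subject {sid!r}")


# ---------------------------------------------------------------------------
# run configuration


class ModelOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    observed_compartment: str = "a3"  # or "a1+a3"
    gamma_estimated: bool = False
    wt_ref: float = 1.0
    iiv_convention: str = "cv"  # or "sd"


class EstimationOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: str = "agq"
    n_nodes: int = 9
    n_starts: int = 1
    optimizer: str = "lbfgs"
    maxiter: int = 400


class SimulationOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_sim: int = 200
    seed: int = 0


class RunConfig(BaseModel):
    """Declarative run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    model: ModelOptions = ModelOptions()
    estimation: EstimationOptions = EstimationOptions()
    simulation: SimulationOptions = SimulationOptions()
    out_dir: str = "."


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# fit results and manifests


def fit_result_to_dict(res: FitResult) -> dict:
    return {
        "estimates": res.estimates,
        "se": {k: None if np.isnan(v) else v for k, v in res.se.items()},
        "rse_percent": {
            k: None if np.isnan(v) else v for k, v in res.rse_percent.items()
        },
        "fixed": res.fixed,
        "neg2ll": res.neg2ll,
        "converged": res.converged,
        "message": res.message,
        "n_evals": res.n_evals,
        "n_subjects": res.n_subjects,
        "n_obs": res.n_obs,
        "etas": res.etas,
        "method": res.spec.method,
        "observables": list(res.spec.observables),
    }


def write_fit_result(res: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(res), indent=2) + "\n")


def write_manifest(path, command: str, args: dict, seed: int | None) -> None:
    """Reproducibility manifest written alongside every CLI artifact."""
    from . import __version__

    payload = {
        "command": command,
        "args": {k: str(v) for k, v in sorted(args.items())},
        "seed": seed,
        "package_version": __version__,
    }
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]
    payload["config_hash"] = digest
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
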