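"""Between-subject variability and residual error.

The reference analysis supports a single log-normal random effect, on the
plasma-return clearance CL32 (the parameter governing redistribution back
into the observed compartment), plus proportional residual error per
observable.  Interindividual variability is reported as a CV%, interpreted
here as the exact log-normal coefficient of variation
CV% = 100·sqrt(exp(ω²) − 1); the alternative 100·ω convention is available
through ``omega_from_iiv_percent``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas

from ._rng import substream
from .structural import (
    BiomarkerParams,
    DoseEvent,
    PDParams,
    PKParams,
    ScaledPK,
    allometric_scale,
    biomarker_level,
    simulate_pkpd,
    with_cl32,
    CONC_SCALE,
)

__all__ = [
    "PopulationParams",
    "Individual",
    "SubjectDesign",
    "draw_etas",
    "cv_from_omega",
    "omega_from_cv",
    "omega_from_iiv_percent",
    "individual_params",
    "apply_residual_error",
    "simulate_population",
    "DATASET_COLUMNS",
    "OBSERVABLES",
]

logger = logging.getLogger(__name__)

#: controlled vocabulary for the DVID column
OBSERVABLES = ("mrna", "pcc", "2mc", "3hp", "c3c2")

DATASET_COLUMNS = [
    "ID",
    "TIME",
    "EVID",
    "AMT",
    "RATE",
    "DV",
    "DVID",
    "MDV",
    "BLQ",
    "LLOQ",
    "WT",
    "SPECIES",
]


@dataclass
class PopulationParams:
    """ω (SD of the log-normal random effect on CL32) and proportional
    residual-error SDs.  ``sigma_prop`` applies to every observable unless
    overridden per DVID in ``sigma_extra``."""

    omega_cl32: float
    sigma_prop: float
    sigma_extra: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.omega_cl32 < 0:
            raise ValueError("omega_cl32 must be non-negative")
        if self.sigma_prop < 0:
            raise ValueError("sigma_prop must be non-negative")

    def sigma_for(self, dvid: str) -> float:
        return self.sigma_extra.get(dvid, self.sigma_prop)


@dataclass
class Individual:
    id: str
    wt: float
    eta_cl32: float | None = None  # None -> drawn at simulation time
    species: str = "mouse"

    def __post_init__(self):
        if self.wt <= 0:
            raise ValueError(f"subject {self.id!r}: wt must be > 0")


@dataclass
class SubjectDesign:
    """One subject's dosing and sampling plan.

    ``doses`` are (time h, dose mg/kg, infusion duration h) triples —
    amounts are converted to absolute mg with the subject's weight at
    simulation time.  ``sampling`` maps DVID -> observation times,
    ``lloq`` maps DVID -> lower limit of quantification (omit for none).
    """

    individual: Individual
    doses: list[tuple[float, float, float]]
    sampling: dict[str, np.ndarray]
    lloq: dict[str, float] = field(default_factory=dict)


def draw_etas(pop: PopulationParams, n: int, seed: int) -> np.ndarray:
    """n i.i.d. Normal(0, ω²) draws from the 'eta' substream of ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = substream(seed, "eta")
    return rng.normal(0.0, pop.omega_cl32, size=n)


def cv_from_omega(omega: float) -> float:
    """Log-normal CV%% implied by a log-scale SD ω."""
    if omega < 0:
        raise ValueError("omega must be non-negative")
    return 100.0 * np.sqrt(np.expm1(omega**2))


def omega_from_cv(cv_percent: float) -> float:
    """Log-scale SD ω implied by a log-normal CV%% (exact inverse of
    :func:`cv_from_omega`)."""
    if cv_percent < 0:
        raise ValueError("cv must be non-negative")
    return float(np.sqrt(np.log1p((cv_percent / 100.0) ** 2)))


def omega_from_iiv_percent(iiv_percent: float, convention: str = "cv") -> float:
    """Convert a reported IIV percentage to ω under either reporting
    convention: ``"cv"`` (exact log-normal CV%) or ``"sd"`` (100·ω)."""
    if convention == "cv":
        return omega_from_cv(iiv_percent)
    if convention == "sd":
        return iiv_percent / 100.0
    raise ValueError(f"unknown IIV convention {convention!r}")


def individual_params(pk: PKParams, ind: Individual) -> ScaledPK:
    """Allometrically scaled parameters for one subject with the random
    effect applied: CL32 ← CL32·exp(η)."""
    sc = allometric_scale(pk, ind.wt, subject=ind.id)
    eta = 0.0 if ind.eta_cl32 is None else ind.eta_cl32
    return with_cl32(sc, float(np.exp(eta)))


def apply_residual_error(
    predictions: np.ndarray,
    sigma_prop: float,
    seed_or_rng,
) -> np.ndarray:
    """y = f·(1 + ε), ε ~ Normal(0, σ²); negative results are floored at 0
    (logged, rare at the default σ)."""
    f = np.asarray(predictions, dtype=float)
    if np.any(f < 0):
        raise ValueError("predictions must be non-negative")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    y = f * (1.0 + rng.normal(0.0, sigma_prop, size=f.shape))
    n_floored = int(np.sum(y < 0))
    if n_floored:
        logger.info("floored %d negative simulated observations at 0", n_floored)
    return np.clip(y, 0.0, None)


def _dose_events(design: SubjectDesign) -> list[DoseEvent]:
    wt = design.individual.wt
    events = [DoseEvent(t, per_kg * wt, dur) for (t, per_kg, dur) in design.doses]
    infusions = sorted(
        ((d.time, d.time + d.duration) for d in events if d.duration > 0)
    )
    for (s0, e0), (s1, _) in zip(infusions, infusions[1:]):
        if s1 < e0:
            raise ValueError(
                f"subject {design.individual.id!r}: overlapping infusions"
            )
    return events


def simulate_population(
    pk: PKParams,
    pd: PDParams,
    biomarkers: dict[str, BiomarkerParams],
    pop: PopulationParams,
    cohort: list[SubjectDesign],
    seed: int,
    conc_scale: float = CONC_SCALE,
    method: str = "closed_form",
) -> pandas.DataFrame:
    """Simulate a cohort into a long-format NONMEM-convention dataset.

    One record per dose event and per subject/time/observable; DV carries
    proportional residual error; values below an observable's LLOQ are
    emitted as BLQ records (DV set to the LLOQ, BLQ = 1).  Fully
    deterministic given ``seed``: each subject's random effect and each
    subject×observable residual vector come from named substreams.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    rows: list[dict] = []
    for design in cohort:
        ind = design.individual
        eta = ind.eta_cl32
        if eta is None:
            eta = float(substream(seed, "eta", ind.id).normal(0.0, pop.omega_cl32))
        rates = with_cl32(allometric_scale(pk, ind.wt, subject=ind.id), np.exp(eta))
        doses = _dose_events(design)
        for d in doses:
            rows.append(
                dict(
                    ID=ind.id,
                    TIME=d.time,
                    EVID=1,
                    AMT=d.amount,
                    RATE=d.amount / d.duration if d.duration > 0 else 0.0,
                    DV=np.nan,
                    DVID=".",
                    MDV=1,
                    BLQ=0,
                    LLOQ=np.nan,
                    WT=ind.wt,
                    SPECIES=ind.species,
                )
            )
        union = np.unique(np.concatenate([np.asarray(t, float) for t in design.sampling.values()]))
        traj = simulate_pkpd(
            pk, pd, ind.wt, doses, union, method=method,
            conc_scale=conc_scale, rates=rates,
        )
        for dvid, t_obs in design.sampling.items():
            t_obs = np.asarray(t_obs, dtype=float)
            idx = np.searchsorted(union, t_obs)
            if dvid == "mrna":
                f = traj["conc"][idx]
            elif dvid == "pcc":
                f = traj["p_total"][idx]
            elif dvid in biomarkers:
                f = biomarker_level(traj["p_total"][idx], biomarkers[dvid])
            else:
                raise ValueError(f"no biomarker parameters for observable {dvid!r}")
            rng = substream(seed, "residual", ind.id, dvid)
            y = apply_residual_error(f, pop.sigma_for(dvid), rng)
            lloq = design.lloq.get(dvid)
            for t, yv in zip(t_obs, y):
                blq = int(lloq is not None and yv < lloq)
                rows.append(
                    dict(
                        ID=ind.id,
                        TIME=t,
                        EVID=0,
                        AMT=np.nan,
                        RATE=np.nan,
                        DV=lloq if blq else yv,
                        DVID=dvid,
                        MDV=0,
                        BLQ=blq,
                        LLOQ=np.nan if lloq is None else lloq,
                        WT=ind.wt,
                        SPECIES=ind.species,
                    )
                )
    df = pandas.DataFrame(rows, columns=DATASET_COLUMNS)
    # stable ordering: subject, time, doses before observations at ties
    df = df.sort_values(
        ["ID", "TIME", "EVID", "DVID"], ascending=[True, True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df
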