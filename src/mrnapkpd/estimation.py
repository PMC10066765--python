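"""Nonlinear mixed-effects estimation.

Maximum-likelihood estimation of typical PK/PD parameters from long-format
datasets with a single scalar log-normal random effect (on CL32) and
proportional residual error.  The per-subject marginal likelihood

    L_i = ∫ p(y_i | η) φ(η; 0, ω²) dη

is evaluated by the Laplace approximation or by adaptive Gauss–Hermite
quadrature (AGQ) centred at the empirical-Bayes mode.  With one scalar
random effect AGQ at 9+ nodes is effectively exact, which is why it stands
in for linearisation-based conditional methods (FOCEI): the target is the
model's maximum-likelihood estimates, not a particular software objective.

Observations below the limit of quantification contribute censored-normal
terms Φ((LLOQ − f)/(σ·f)) — the M3 method — or can be discarded for
sensitivity analysis.

Standard errors come from the inverse of a central finite-difference
Hessian of −2·log L at the optimum, delta-scaled back to the natural
parameter scale.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas
from scipy.optimize import minimize, minimize_scalar
from scipy.special import log_ndtr, logsumexp

from ._rng import substream
from .population import PopulationParams, apply_residual_error, OBSERVABLES
from .structural import (
    BiomarkerParams,
    DoseEvent,
    PDParams,
    PKParams,
    allometric_scale,
    biomarker_level,
    pk_matrix,
    pkpd_matrix,
    with_cl32,
    CONC_SCALE,
)
from ._linalg import linear_trajectory

__all__ = [
    "ModelParameters",
    "FitSpec",
    "FitResult",
    "subject_marginal_loglik",
    "fit",
    "compute_diagnostics",
    "vpc",
    "extract_design",
]

logger = logging.getLogger(__name__)

#: absolute floor on the residual variance (σ·f)² so the likelihood stays
#: finite when the structural prediction is exactly zero
VARIANCE_FLOOR = 1e-10

# parameters estimated on the identity scale (may legitimately approach any
# real value); everything else is log-transformed for positivity
_IDENTITY_PARAMS = {"cl_alpha", "cl_beta", "v_exponent"}

_PK_NAMES = (
    "tvcl12",
    "tvcl23",
    "tvcl32",
    "tvcl20",
    "tvv",
    "tvv2",
    "cl_alpha",
    "cl_beta",
    "v_exponent",
    "wt_ref",
)
_PD_NAMES = ("ke0", "ksyn_slope", "kdeg", "kq", "p_baseline")
_BM_FIELDS = ("e0", "base", "ic50", "imax", "gamma")


@dataclass
class ModelParameters:
    """A full parameter bundle: disposition, protein PD, biomarker response
    and population variability.  Parameters are addressed by flat names
    (``"tvcl12"``, ``"ke0"``, ``"ic50_2mc"``, ``"omega_cl32"``,
    ``"sigma_mrna"``, ...) so fit specifications stay declarative."""

    pk: PKParams
    pd: PDParams | None = None
    biomarkers: dict[str, BiomarkerParams] = field(default_factory=dict)
    pop: PopulationParams | None = None

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    def get(self, name: str) -> float:
        obj, attr = self._locate(name)
        if attr.startswith("sigma:"):
            return self.pop.sigma_extra.get(attr.split(":", 1)[1], self.pop.sigma_prop)
        return getattr(obj, attr)

    def set(self, name: str, value: float) -> None:
        obj, attr = self._locate(name)
        if attr.startswith("sigma:"):
            self.pop.sigma_extra[attr.split(":", 1)[1]] = value
        else:
            setattr(obj, attr, value)

    def _locate(self, name: str):
        if name in _PK_NAMES:
            return self.pk, name
        if name in _PD_NAMES:
            if self.pd is None:
                raise KeyError(f"{name}: model has no PD parameters")
            return self.pd, name
        if name == "omega_cl32":
            return self.pop, "omega_cl32"
        if name.startswith("sigma_"):
            dvid = name[len("sigma_"):]
            if dvid in ("mrna", "prop"):
                return self.pop, "sigma_prop"
            return self.pop, f"sigma:{dvid}"
        for fieldname in _BM_FIELDS:
            prefix = fieldname + "_"
            if name.startswith(prefix):
                bm = name[len(prefix):]
                if bm not in self.biomarkers:
                    raise KeyError(f"{name}: no biomarker {bm!r} in model")
                return self.biomarkers[bm], fieldname
        raise KeyError(f"unknown parameter name {name!r}")


def _sigma_lookup(model: ModelParameters, dvid: str) -> float:
    if dvid == "mrna":
        return model.pop.sigma_prop
    return model.pop.sigma_extra.get(dvid, model.pop.sigma_prop)


@dataclass
class FitSpec:
    """What to estimate and how.

    ``free`` maps parameter names to initial values; ``fixed`` values are
    applied to the model before fitting and reported as "Fixed" (the
    two-step scheme used for the volumes and Imax in the reference
    analysis).  ``method`` is ``"laplace"``, ``"agq"`` or ``"focei"``
    (accepted as an alias for AGQ — see module docstring).
    """

    free: dict[str, float]
    fixed: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    method: str = "agq"
    n_nodes: int = 9
    observables: tuple[str, ...] = ("mrna",)
    blq_policy: str = "m3"  # or "discard"
    optimizer: str = "lbfgs"  # or "neldermead", "powell"
    n_starts: int = 1
    maxiter: int = 400
    compute_se: bool = True

    def __post_init__(self):
        if not self.free:
            raise ValueError("at least one free parameter is required")
        if self.method not in ("laplace", "agq", "focei"):
            raise ValueError(f"unknown estimation method {self.method!r}")
        if self.blq_policy not in ("m3", "discard"):
            raise ValueError(f"unknown BLQ policy {self.blq_policy!r}")
        for name, (lo, hi) in self.bounds.items():
            x0 = self.free.get(name)
            if x0 is not None and not (lo <= x0 <= hi):
                raise ValueError(f"initial value for {name} outside bounds")


@dataclass
class FitResult:
    """Estimates with uncertainty and goodness-of-fit metadata."""

    estimates: dict[str, float]
    se: dict[str, float]
    rse_percent: dict[str, float]
    fixed: dict[str, str]
    neg2ll: float
    converged: bool
    message: str
    n_evals: int
    model: ModelParameters
    spec: FitSpec
    etas: dict[str, float] = field(default_factory=dict)
    n_subjects: int = 0
    n_obs: int = 0

    def summary(self) -> pandas.DataFrame:
        """Parameter-table view (estimate, %RSE; fixed parameters flagged)."""
        rows = [
            {
                "parameter": k,
                "estimate": v,
                "se": self.se.get(k, np.nan),
                "rse_percent": self.rse_percent.get(k, np.nan),
                "status": "estimated",
            }
            for k, v in self.estimates.items()
        ]
        rows += [
            {
                "parameter": k,
                "estimate": self.model.get(k),
                "se": np.nan,
                "rse_percent": np.nan,
                "status": "Fixed",
            }
            for k in self.fixed
        ]
        return pandas.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset -> per-subject working representation


class _Subject:
    """Pre-parsed per-subject data: dose events, observation arrays and the
    union time grid the trajectory is evaluated on."""

    __slots__ = (
        "id",
        "wt",
        "species",
        "doses",
        "obs_time",
        "obs_dvid",
        "obs_dv",
        "obs_blq",
        "obs_lloq",
        "union_times",
        "union_idx",
        "needs_pd",
        "groups",
    )

    def __init__(self, sid, records: pandas.DataFrame, observables, blq_policy):
        self.id = sid
        self.wt = float(records["WT"].iloc[0])
        self.species = str(records["SPECIES"].iloc[0])
        dose_rows = records[records["EVID"] == 1]
        self.doses = [
            DoseEvent(
                float(r.TIME),
                float(r.AMT),
                float(r.AMT) / float(r.RATE) if r.RATE and r.RATE > 0 else 0.0,
            )
            for r in dose_rows.itertuples()
        ]
        obs = records[(records["EVID"] == 0) & records["DVID"].isin(observables)]
        if blq_policy == "discard":
            obs = obs[obs["BLQ"] == 0]
        self.obs_time = obs["TIME"].to_numpy(dtype=float)
        self.obs_dvid = obs["DVID"].to_numpy(dtype=object)
        self.obs_dv = obs["DV"].to_numpy(dtype=float)
        self.obs_blq = obs["BLQ"].to_numpy(dtype=int)
        self.obs_lloq = obs["LLOQ"].to_numpy(dtype=float)
        self.union_times = np.unique(self.obs_time)
        self.union_idx = np.searchsorted(self.union_times, self.obs_time)
        self.needs_pd = bool(np.any(self.obs_dvid != "mrna"))
        # per-observable record groups, precomputed for the likelihood loop
        self.groups = []
        for dvid in np.unique(self.obs_dvid):
            sel = np.flatnonzero(self.obs_dvid == dvid)
            blq = self.obs_blq[sel] == 1
            self.groups.append(
                (
                    str(dvid),
                    sel,
                    self.union_idx[sel],
                    self.obs_dv[sel],
                    blq,
                    self.obs_lloq[sel],
                )
            )

    @property
    def n_obs(self) -> int:
        return int(self.obs_time.size)


def _split_subjects(
    dataset: pandas.DataFrame, observables, blq_policy
) -> list[_Subject]:
    subjects = []
    for sid, grp in dataset.groupby("ID", sort=True):
        s = _Subject(sid, grp, observables, blq_policy)
        if s.n_obs > 0:
            subjects.append(s)
    if not subjects:
        raise ValueError(
            f"dataset contains no observations for observables {tuple(observables)}"
        )
    return subjects


def _predict_subject(
    model: ModelParameters,
    subj: _Subject,
    eta: float,
    conc_scale: float = CONC_SCALE,
) -> np.ndarray:
    """Structural predictions aligned with the subject's observation records
    for a given value of the random effect."""
    rates = with_cl32(
        allometric_scale(model.pk, subj.wt, subject=subj.id), math.exp(eta)
    )
    if subj.needs_pd:
        A = pkpd_matrix(rates, model.pd, conc_scale)
        x0 = np.zeros(6)
        x0[4] = x0[5] = model.pd.p_baseline / 2.0
        states = linear_trajectory(A, x0, subj.doses, subj.union_times)
        conc = np.clip(states[:, 2], 0.0, None) / rates.v * conc_scale
        p_total = np.clip(states[:, 4] + states[:, 5], 0.0, None)
    else:
        states = linear_trajectory(
            pk_matrix(rates), np.zeros(3), subj.doses, subj.union_times
        )
        conc = np.clip(states[:, 2], 0.0, None) / rates.v * conc_scale
        p_total = None

    f = np.empty(subj.n_obs)
    for dvid, sel, idx, _, _, _ in subj.groups:
        if dvid == "mrna":
            f[sel] = conc[idx]
        elif dvid == "pcc":
            f[sel] = p_total[idx]
        else:
            f[sel] = biomarker_level(p_total[idx], model.biomarkers[dvid])
    return f


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _conditional_loglik(subj: _Subject, f: np.ndarray, model: ModelParameters) -> float:
    """log p(y | η): normal density for quantified records, censored-normal
    (M3) for BLQ records, with a variance floor at f = 0."""
    ll = 0.0
    for dvid, sel, _, dv, blq, lloq in subj.groups:
        sigma = _sigma_lookup(model, dvid)
        fv = f[sel]
        sd = np.sqrt((sigma * fv) ** 2 + VARIANCE_FLOOR)
        if blq.any():
            quant = ~blq
            z = (dv[quant] - fv[quant]) / sd[quant]
            ll += float(
                np.sum(-np.log(sd[quant]) - 0.5 * z * z) - _LOG_SQRT_2PI * z.size
            )
            ll += float(np.sum(log_ndtr((lloq[blq] - fv[blq]) / sd[blq])))
        else:
            z = (dv - fv) / sd
            ll += float(np.sum(-np.log(sd) - 0.5 * z * z) - _LOG_SQRT_2PI * z.size)
    return ll


_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gh_nodes(n: int):
    if n not in _GH_CACHE:
        _GH_CACHE[n] = np.polynomial.hermite.hermgauss(n)
    return _GH_CACHE[n]


def _eta_mode(joint, omega: float, bracket: float = 8.0):
    """Mode and curvature of the joint log-density g(η) = log p(y|η) + log φ(η)."""
    res = minimize_scalar(
        lambda e: -joint(e),
        bounds=(-bracket * omega, bracket * omega),
        method="bounded",
        options={"xatol": 1e-9},
    )
    eta_hat = float(res.x)
    h = 1e-3 * max(omega, 0.1)
    g0 = joint(eta_hat)
    gp = joint(eta_hat + h)
    gm = joint(eta_hat - h)
    curv = -(gp - 2.0 * g0 + gm) / h**2  # -g''(η̂) > 0 at a maximum
    if not np.isfinite(curv) or curv <= 0:
        curv = 1.0 / omega**2
    return eta_hat, curv, g0


def subject_marginal_loglik(
    subject_records: pandas.DataFrame,
    model: ModelParameters,
    method: str = "agq",
    n_nodes: int = 9,
    observables: tuple[str, ...] | None = None,
    blq_policy: str = "m3",
    conc_scale: float = CONC_SCALE,
    _subject: _Subject | None = None,
    return_eta: bool = False,
):
    """Marginal log-likelihood of one subject's records.

    Marginalises the scalar random effect on CL32 by the Laplace
    approximation (``method="laplace"``) or adaptive Gauss–Hermite
    quadrature (``"agq"``/``"focei"``, default 9 nodes).  With ω ≈ 0 the
    marginal degenerates to the conditional log-likelihood at η = 0.
    """
    if _subject is None:
        if observables is None:
            observables = tuple(
                d for d in OBSERVABLES
                if d in set(subject_records["DVID"].unique())
            )
        subj = _Subject(
            str(subject_records["ID"].iloc[0]), subject_records, observables, blq_policy
        )
        if subj.n_obs == 0:
            raise ValueError("subject has no usable observations")
    else:
        subj = _subject
    omega = model.pop.omega_cl32

    def joint(eta: float) -> float:
        f = _predict_subject(model, subj, eta, conc_scale)
        ll = _conditional_loglik(subj, f, model)
        if omega > 0:
            ll += -math.log(omega) - _LOG_SQRT_2PI - 0.5 * (eta / omega) ** 2
        return ll

    if omega < 1e-8:
        f = _predict_subject(model, subj, 0.0, conc_scale)
        out = _conditional_loglik(subj, f, model)
        return (out, 0.0) if return_eta else out

    eta_hat, curv, g_hat = _eta_mode(joint, omega)
    if method == "laplace":
        out = g_hat + 0.5 * math.log(2.0 * math.pi / curv)
    else:
        x, w = _gh_nodes(n_nodes)
        scale = math.sqrt(2.0 / curv)
        g_vals = np.array([joint(eta_hat + scale * xi) for xi in x])
        out = float(logsumexp(g_vals + x**2 + np.log(w))) + math.log(scale)
    if not np.isfinite(out):
        raise FloatingPointError(
            f"non-finite marginal likelihood for subject {subj.id!r}"
        )
    return (out, eta_hat) if return_eta else out


# ---------------------------------------------------------------------------
# fitting


def _transform(name: str, value: float) -> float:
    return value if name in _IDENTITY_PARAMS else math.log(value)


def _untransform(name: str, value: float) -> float:
    return value if name in _IDENTITY_PARAMS else math.exp(value)


def _neg2ll(
    theta: np.ndarray,
    names: list[str],
    model: ModelParameters,
    subjects: list[_Subject],
    spec: FitSpec,
    conc_scale: float,
) -> float:
    m = model
    for name, t in zip(names, theta):
        m.set(name, _untransform(name, float(t)))
    total = 0.0
    try:
        for s in subjects:
            total += subject_marginal_loglik(
                None,
                m,
                method=spec.method,
                n_nodes=spec.n_nodes,
                blq_policy=spec.blq_policy,
                conc_scale=conc_scale,
                _subject=s,
            )
    except (FloatingPointError, OverflowError, np.linalg.LinAlgError):
        return 1e12
    if not np.isfinite(total):
        return 1e12
    return -2.0 * total


def fit(
    dataset: pandas.DataFrame,
    spec: FitSpec,
    model0: ModelParameters,
    conc_scale: float = CONC_SCALE,
) -> FitResult:
    """Maximum-likelihood fit of the free parameters in ``spec``.

    Positive parameters are optimised on the log scale; the optimiser is
    quasi-Newton (L-BFGS-B) by default with derivative-free fallbacks, and
    optional jittered multi-starts guard against local minima (lowest −2LL
    wins).  Deterministic given dataset, spec and settings.
    """
    model = model0.copy()
    for name, value in spec.fixed.items():
        model.set(name, value)
    subjects = _split_subjects(dataset, spec.observables, spec.blq_policy)
    names = list(spec.free)
    theta0 = np.array([_transform(n, v) for n, v in spec.free.items()])
    tbounds = [
        (
            _transform(n, spec.bounds[n][0]) if n in spec.bounds else -np.inf,
            _transform(n, spec.bounds[n][1]) if n in spec.bounds else np.inf,
        )
        for n in names
    ]

    n_evals = 0

    def objective(theta):
        nonlocal n_evals
        n_evals += 1
        return _neg2ll(theta, names, model, subjects, spec, conc_scale)

    starts = [theta0]
    if spec.n_starts > 1:
        rng = substream(0, "fit-multistart")
        starts += [
            theta0 + rng.normal(0.0, 0.2, size=theta0.size)
            for _ in range(spec.n_starts - 1)
        ]

    best = None
    for k, start in enumerate(starts):
        if spec.optimizer == "lbfgs":
            res = minimize(
                objective,
                start,
                method="L-BFGS-B",
                bounds=tbounds,
                options={
                    "maxiter": spec.maxiter,
                    "ftol": 1e-10,
                    "gtol": 1e-6,
                    "eps": 1e-5,
                },
            )
        elif spec.optimizer == "neldermead":
            res = minimize(
                objective,
                start,
                method="Nelder-Mead",
                options={"maxiter": spec.maxiter * len(names), "xatol": 1e-6, "fatol": 1e-8, "adaptive": True},
            )
        elif spec.optimizer == "powell":
            res = minimize(
                objective,
                start,
                method="Powell",
                bounds=tbounds,
                options={"maxiter": spec.maxiter, "xtol": 1e-8, "ftol": 1e-10},
            )
        else:
            raise ValueError(f"unknown optimizer {spec.optimizer!r}")
        logger.info("start %d: -2LL = %.4f (%s)", k, res.fun, res.message)
        if best is None or res.fun < best.fun:
            best = res

    theta_hat = np.asarray(best.x, dtype=float)
    converged = bool(best.success)
    for name, t in zip(names, theta_hat):
        model.set(name, _untransform(name, float(t)))
    estimates = {n: model.get(n) for n in names}

    se: dict[str, float] = {n: np.nan for n in names}
    rse: dict[str, float] = {n: np.nan for n in names}
    if spec.compute_se:
        se_t = _hessian_se(objective, theta_hat)
        if se_t is not None:
            for n, t, s in zip(names, theta_hat, se_t):
                # delta method back to natural scale for log-parameters
                se[n] = s * estimates[n] if n not in _IDENTITY_PARAMS else s
                rse[n] = 100.0 * se[n] / abs(estimates[n])
        else:
            logger.warning("Hessian not positive definite; SEs unavailable")

    etas = {}
    for s in subjects:
        _, eta_hat = subject_marginal_loglik(
            None,
            model,
            method=spec.method,
            n_nodes=spec.n_nodes,
            blq_policy=spec.blq_policy,
            conc_scale=conc_scale,
            _subject=s,
            return_eta=True,
        )
        etas[s.id] = eta_hat

    return FitResult(
        estimates=estimates,
        se=se,
        rse_percent=rse,
        fixed={n: "Fixed" for n in spec.fixed},
        neg2ll=float(best.fun),
        converged=converged,
        message=str(best.message),
        n_evals=n_evals,
        model=model,
        spec=spec,
        etas=etas,
        n_subjects=len(subjects),
        n_obs=sum(s.n_obs for s in subjects),
    )


def _hessian_se(objective, theta: np.ndarray, step: float = 1e-3):
    """SEs on the transformed scale from the inverse Hessian of −2LL
    (0.5·H is the observed information)."""
    k = theta.size
    H = np.empty((k, k))
    f0 = objective(theta)

    def f_at(offsets):
        t = theta.copy()
        for i, d in offsets:
            t[i] += d
        return objective(t)

    for i in range(k):
        H[i, i] = (f_at([(i, step)]) - 2.0 * f0 + f_at([(i, -step)])) / step**2
        for j in range(i + 1, k):
            fpp = f_at([(i, step), (j, step)])
            fpm = f_at([(i, step), (j, -step)])
            fmp = f_at([(i, -step), (j, step)])
            fmm = f_at([(i, -step), (j, -step)])
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step**2)
    info = 0.5 * H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None
    d = np.diag(cov)
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        return None
    return np.sqrt(d)


# ---------------------------------------------------------------------------
# diagnostics


def compute_diagnostics(
    dataset: pandas.DataFrame,
    fitres: FitResult,
    conc_scale: float = CONC_SCALE,
) -> pandas.DataFrame:
    """Per-record PRED, IPRED and CWRES for the non-BLQ observations.

    PRED is the typical-subject prediction (η = 0), IPRED the prediction at
    the empirical-Bayes η, and CWRES the conditional weighted residual from
    the first-order linearisation of the residual covariance about η̂.
    BLQ records are excluded (count in ``.attrs["n_blq_excluded"]``).
    """
    model = fitres.model
    spec = fitres.spec
    subjects = _split_subjects(dataset, spec.observables, "m3")
    rows = []
    n_blq = 0
    omega = model.pop.omega_cl32
    for s in subjects:
        _, eta_hat = subject_marginal_loglik(
            None, model, method=spec.method, n_nodes=spec.n_nodes,
            conc_scale=conc_scale, _subject=s, return_eta=True,
        )
        f_pred = _predict_subject(model, s, 0.0, conc_scale)
        f_ipred = _predict_subject(model, s, eta_hat, conc_scale)
        h = 1e-4 * max(omega, 0.1)
        grad = (
            _predict_subject(model, s, eta_hat + h, conc_scale)
            - _predict_subject(model, s, eta_hat - h, conc_scale)
        ) / (2.0 * h)
        keep = s.obs_blq == 0
        n_blq += int(np.sum(~keep))
        sig = np.array([_sigma_lookup(model, d) for d in s.obs_dvid])
        Rdiag = (sig * f_ipred) ** 2 + VARIANCE_FLOOR
        g = grad[keep]
        V = np.outer(g, g) * omega**2 + np.diag(Rdiag[keep])
        L = np.linalg.cholesky(V)
        resid = s.obs_dv[keep] - f_ipred[keep] + g * eta_hat
        cwres = np.linalg.solve(L, resid)
        times = s.obs_time[keep]
        dvids = s.obs_dvid[keep]
        dvs = s.obs_dv[keep]
        for i in range(times.size):
            rows.append(
                dict(
                    ID=s.id,
                    TIME=times[i],
                    DVID=dvids[i],
                    DV=dvs[i],
                    PRED=f_pred[keep][i],
                    IPRED=f_ipred[keep][i],
                    CWRES=cwres[i],
                    ETA=eta_hat,
                )
            )
    out = pandas.DataFrame(rows)
    out.attrs["n_blq_excluded"] = n_blq
    return out


# ---------------------------------------------------------------------------
# visual predictive check


def extract_design(dataset: pandas.DataFrame):
    """Recover the simulation design (subjects, doses, sampling, LLOQ) from a
    long-format dataset, for re-simulation."""
    from .population import Individual, SubjectDesign

    designs = []
    for sid, grp in dataset.groupby("ID", sort=True):
        wt = float(grp["WT"].iloc[0])
        species = str(grp["SPECIES"].iloc[0])
        doses = []
        for r in grp[grp["EVID"] == 1].itertuples():
            dur = float(r.AMT) / float(r.RATE) if r.RATE and r.RATE > 0 else 0.0
            doses.append((float(r.TIME), float(r.AMT) / wt, dur))
        obs = grp[grp["EVID"] == 0]
        sampling = {}
        lloq = {}
        for dvid, og in obs.groupby("DVID"):
            sampling[dvid] = og["TIME"].to_numpy(dtype=float)
            ll = og["LLOQ"].dropna()
            if not ll.empty:
                lloq[dvid] = float(ll.iloc[0])
        designs.append(
            SubjectDesign(
                individual=Individual(id=str(sid), wt=wt, species=species),
                doses=doses,
                sampling=sampling,
                lloq=lloq,
            )
        )
    return designs


def vpc(
    dataset: pandas.DataFrame,
    fitres_or_model,
    n_sim: int = 200,
    seed: int = 0,
    percentiles: tuple[float, float, float] = (5.0, 50.0, 95.0),
    conc_scale: float = CONC_SCALE,
) -> pandas.DataFrame:
    """Visual predictive check: re-simulate the dataset's design ``n_sim``
    times at the fitted (or given) parameters and compare observed
    percentiles with the simulated percentile bands per time bin.

    Simulated values below an observable's LLOQ are censored at the LLOQ
    before percentiles are computed, matching how BLQ observations enter
    the observed data.  Returns one row per (DVID, time bin) with observed
    percentiles, pooled simulated percentiles, the across-replicate 90%
    interval of the replicate median, and an ``all_blq`` flag.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    model = fitres_or_model.model if isinstance(fitres_or_model, FitResult) else fitres_or_model
    designs = extract_design(dataset)
    lo, mid, hi = percentiles

    obs = dataset[dataset["EVID"] == 0].copy()
    sims: dict[tuple[str, float], list[np.ndarray]] = {}
    rep_medians: dict[tuple[str, float], np.ndarray] = {}

    # simulate replicate datasets (per-subject trajectories with fresh etas
    # and residuals each replicate)
    per_bin_sim: dict[tuple[str, float], list[list[float]]] = {}
    for rep in range(n_sim):
        for di, design in enumerate(designs):
            ind = design.individual
            eta = float(
                substream(seed, "vpc-eta", rep, ind.id).normal(
                    0.0, model.pop.omega_cl32
                )
            )
            rates = with_cl32(
                allometric_scale(model.pk, ind.wt, subject=ind.id), math.exp(eta)
            )
            doses = [DoseEvent(t, pk_mgkg * ind.wt, dur) for t, pk_mgkg, dur in design.doses]
            union = np.unique(
                np.concatenate([np.asarray(t, float) for t in design.sampling.values()])
            )
            if model.pd is not None:
                A = pkpd_matrix(rates, model.pd, conc_scale)
                x0 = np.zeros(6)
                x0[4] = x0[5] = model.pd.p_baseline / 2.0
                states = linear_trajectory(A, x0, doses, union)
                conc = np.clip(states[:, 2], 0.0, None) / rates.v * conc_scale
                p_total = np.clip(states[:, 4] + states[:, 5], 0.0, None)
            else:
                states = linear_trajectory(pk_matrix(rates), np.zeros(3), doses, union)
                conc = np.clip(states[:, 2], 0.0, None) / rates.v * conc_scale
                p_total = None
            for dvid, t_obs in design.sampling.items():
                idx = np.searchsorted(union, np.asarray(t_obs, float))
                if dvid == "mrna":
                    f = conc[idx]
                elif dvid == "pcc":
                    f = p_total[idx]
                else:
                    f = biomarker_level(p_total[idx], model.biomarkers[dvid])
                rng = substream(seed, "vpc-res", rep, ind.id, dvid)
                y = apply_residual_error(f, _sigma_lookup(model, dvid), rng)
                lloq = design.lloq.get(dvid)
                if lloq is not None:
                    y = np.maximum(y, lloq)
                for t, yv in zip(t_obs, y):
                    per_bin_sim.setdefault((dvid, float(t)), [[] for _ in range(n_sim)])[
                        rep
                    ].append(yv)

    rows = []
    for (dvid, t), reps in sorted(per_bin_sim.items()):
        ob = obs[(obs["DVID"] == dvid) & (np.isclose(obs["TIME"], t))]
        if ob.empty:
            continue
        yobs = ob["DV"].to_numpy(dtype=float)
        pooled = np.concatenate([np.asarray(r) for r in reps])
        med_reps = np.array([np.median(r) for r in reps if len(r)])
        lloq_vals = ob["LLOQ"].dropna()
        all_blq = bool((ob["BLQ"] == 1).all())
        rows.append(
            dict(
                DVID=dvid,
                TIME=t,
                n_obs=yobs.size,
                obs_lo=np.percentile(yobs, lo),
                obs_med=np.percentile(yobs, mid),
                obs_hi=np.percentile(yobs, hi),
                sim_lo=np.percentile(pooled, lo),
                sim_med=np.percentile(pooled, mid),
                sim_hi=np.percentile(pooled, hi),
                med_lo=np.percentile(med_reps, lo),
                med_hi=np.percentile(med_reps, hi),
                all_blq=all_blq,
            )
        )
    out = pandas.DataFrame(rows)
    if out.empty:
        raise ValueError("VPC produced no populated time bins")
    return out
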