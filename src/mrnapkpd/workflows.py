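"""Canonical analysis workflows.

The reference analysis is sequential: (1) the interspecies mRNA PK model is
fitted to pooled mouse/rat/monkey data, (2) with PK fixed, the hepatic
protein turnover model is fitted to knockout-mouse PD data, (3) with PK and
protein fixed, each biomarker's Imax model is fitted on its own (the 3-HP
stage with the Laplacian marginalisation, everything else with adaptive
quadrature).  These helpers wire the stages together so scripts, the CLI
and tests all run the same pipeline.
"""

from __future__ import annotations

import pandas

from .estimation import FitResult, FitSpec, ModelParameters, fit

__all__ = ["STAGE_PRESETS", "build_stage_spec", "run_sequential_pipeline"]

STAGE_PRESETS = {
    "pk": dict(
        free=("tvcl12", "tvcl23", "tvcl32", "tvcl20", "cl_alpha", "cl_beta",
              "omega_cl32", "sigma_mrna"),
        fixed=("tvv", "tvv2"),
        observables=("mrna",),
    ),
    "protein": dict(
        free=("ke0", "ksyn_slope", "kdeg", "kq", "sigma_pcc"),
        fixed=(),
        observables=("pcc",),
    ),
    "2mc": dict(
        free=("e0_2mc", "base_2mc", "ic50_2mc", "sigma_2mc"),
        fixed=("imax_2mc",),
        observables=("2mc",),
    ),
    "3hp": dict(
        free=("e0_3hp", "base_3hp", "ic50_3hp", "sigma_3hp"),
        fixed=("imax_3hp",),
        observables=("3hp",),
    ),
    "c3c2": dict(
        free=("e0_c3c2", "base_c3c2", "ic50_c3c2", "sigma_c3c2"),
        fixed=("imax_c3c2",),
        observables=("c3c2",),
    ),
}


def build_stage_spec(
    stage: str, model: ModelParameters, method: str | None = None, **overrides
) -> FitSpec:
    """A FitSpec preset for one stage of the sequential scheme, initialised
    at the supplied model's current parameter values."""
    preset = STAGE_PRESETS[stage]
    if method is None:
        method = "laplace" if stage == "3hp" else "agq"
    return FitSpec(
        free={n: model.get(n) for n in preset["free"]},
        fixed={n: model.get(n) for n in preset["fixed"]},
        observables=preset["observables"],
        method=method,
        **overrides,
    )


def run_sequential_pipeline(
    pk_dataset: pandas.DataFrame,
    pd_dataset: pandas.DataFrame,
    model0: ModelParameters,
    biomarker_stages: tuple[str, ...] = ("2mc", "3hp", "c3c2"),
    compute_se: bool = False,
) -> dict[str, FitResult]:
    """Run the full stepwise fit; each stage starts from, and then updates,
    the working model, so downstream stages see upstream estimates."""
    results: dict[str, FitResult] = {}
    model = model0.copy()

    spec = build_stage_spec("pk", model, compute_se=compute_se)
    results["pk"] = fit(pk_dataset, spec, model)
    model = results["pk"].model

    spec = build_stage_spec("protein", model, compute_se=compute_se)
    results["protein"] = fit(pd_dataset, spec, model)
    model = results["protein"].model

    for stage in biomarker_stages:
        spec = build_stage_spec(stage, model, compute_se=compute_se)
        results[stage] = fit(pd_dataset, spec, model)
        model = results[stage].model
    return results
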