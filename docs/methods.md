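# Methods

This note documents the model, the numerical machinery, the synthetic-data
conditions and the design decisions behind `mrnapkpd`, in the spirit of the
methods documentation of established modelling packages.

## Structural model

**mRNA disposition.** Amounts (mg) in three compartments:

    a1' = −k12·a1 + u(t)                      (dosing compartment, plasma)
    a2' =  k12·a1 + k32·a3 − (k23 + k20)·a2   (tissue)
    a3' =  k23·a2 − k32·a3                    (observed plasma compartment)

with first-order rates derived from clearances and volumes: k12 = CL12/V,
k32 = CL32/V, k23 = CL23/V2, k20 = CL20/V2.  V is shared by the two plasma
compartments; elimination is from tissue only.  The observed concentration
is a3/V (configurable to (a1+a3)/V), scaled by an explicit unit factor
(default 10⁶: mg/mL → ng/mL).  This topology was reconstructed from the
reported rate-constant directions and the requirement that a plasma bolus
produce a *delayed* observed Cmax; the original equation listing is not
public, so the reconstruction is a documented modelling choice rather than
a transcription.  Dosing supports IV bolus (instantaneous addition to a1)
and constant-rate infusion; an observation falling exactly on a bolus time
sees the post-dose state.

**Effect compartment and protein turnover.** The observed concentration
c(t) drives an effect compartment, ce' = ke0·(c − ce), and synthesis of
hepatic PCC protein is a pure linear gain on ce (zero intercept — the
knockout animals express no functional enzyme; a `p_baseline` parameter
exists for hypomorphic models and is split equally between the pools at
t = 0):

    p1' = ksyn_slope·ce − (kdeg + kq)·p1 + kq·p2
    p2' = kq·(p1 − p2)

Degradation acts on the central pool only.  The terminal half-life is
ln 2 / |λ_slow| of the 2×2 turnover matrix; with kq = 0 it reduces to
ln 2 / kdeg.

**Biomarkers.** Each biomarker responds instantaneously to total protein
p = p1 + p2 through e0 + base·(1 − imax·pᵞ/(ic50ᵞ + pᵞ)).  imax is fixed at
0.999; γ defaults to 1 and is estimable (a config flag exposes it — the
qualifier "sigmoidal" in the source analysis may imply γ ≠ 1, but no value
is printed).  The fraction base/(e0 + base) of the pre-treatment level is
amenable to suppression.

## Numerics

The complete PK/PD state (a1, a2, a3, ce, p1, p2) is a linear
time-invariant system with piecewise-constant input, so two solution routes
are provided and cross-checked in the tests:

* `method="lsoda"` — stiff-capable ODE integration (rtol 1e-8, atol 1e-10
  by default, both exposed) with dose times and infusion ends as hard
  integration breakpoints, so bolus discontinuities are reproducible;
* `method="closed_form"` — exact superposition of matrix-exponential
  responses via one eigendecomposition per parameter set, with a piecewise
  `expm` fallback for (near-)defective systems.  This route is what the
  likelihood and population simulators use; it is ~10³× faster and exact.

Negative amounts beyond 1e-6 of the trajectory scale abort with an error;
smaller eigen-/solver noise is clipped at zero.

## Population model and estimation

One log-normal random effect acts on CL32 (the reference analysis
estimated IIV on that parameter alone), and residual error is proportional,
y = f·(1 + ε).  The reported IIV percentage is interpreted as the exact
log-normal CV%, ω = √ln(1 + (CV/100)²) (52.7% → ω = 0.495); the 100·ω
convention is selectable because published tables use both.

The per-subject marginal likelihood ∫ p(y|η) φ(η; 0, ω²) dη is computed by

* **Laplace**: mode η̂ by bounded scalar search (±8ω, tolerance 1e-9),
  curvature by central differences (step 1e-3·max(ω, 0.1));
* **AGQ**: Gauss–Hermite quadrature (default 9 nodes) re-centred and
  re-scaled at (η̂, curvature) — with a single scalar random effect this is
  numerically exact for practical purposes, which is why it stands in for
  linearisation-based conditional estimation (FOCEI): the package targets
  the model's maximum-likelihood estimates, not any specific software's
  objective value.  `method="focei"` is accepted as an alias.

BLQ records contribute censored-normal terms Φ((LLOQ − f)/(σf)) (M3); a
discard-BLQ policy exists for sensitivity analysis.  A variance floor of
1e-10 on (σf)² keeps the likelihood finite at f = 0.  Optimisation is on
log-transformed parameters (allometric exponents on the identity scale) by
L-BFGS-B, with Nelder–Mead and Powell fallbacks and optional jittered
multi-starts (`FitSpec.n_starts`; the default is a single start — the
pipeline's stagewise fits are smooth and low-dimensional, and repeated
starts reproduced the same optimum in exploratory runs, so multi-start is a
guard to enable rather than a default cost).  Standard errors come from the
inverse of a central finite-difference Hessian of −2LL (observed
information; the source table's provenance — sandwich vs information — is
unstated, and this choice is labelled).  Two-step "estimate then fix"
parameters (volumes, Imax) are reported as "Fixed".

Diagnostics follow pharmacometric convention: PRED at η = 0, IPRED at the
empirical-Bayes η̂, CWRES from the first-order conditional linearisation of
the residual covariance about η̂ (BLQ records excluded and counted).  The
VPC re-simulates the dataset design at the fitted parameters, censors
simulated values at each observable's LLOQ, and reports pooled percentile
bands plus the across-replicate interval of the median per time bin, with
all-BLQ bins flagged.

## Sequential workflow

Fitting mirrors the stepwise scheme of the reference analysis: (1)
interspecies mRNA PK (mice + rats + monkeys simultaneously, estimating the
four typical clearances, both allometric exponents, ω and σ, with volumes
fixed); (2) protein turnover (ke0, ksyn_slope, kdeg, kq and the protein σ)
with PK fixed at stage-1 estimates; (3) one Imax model per biomarker (e0,
base, ic50, σ; Imax fixed at 0.999), with the 3-HP stage using the Laplace
marginalisation (matching the reference method choice for that heavily
censored endpoint) and everything else AGQ.  A joint refit is possible by
composing a custom `FitSpec` but is not the default.

## Synthetic-data conditions

The generator's defaults are the study conditions of the reported program:

| item | value | provenance |
| --- | --- | --- |
| tvCL12, tvCL23, tvCL32, tvCL20 | 19.7 / 0.215 / 2.96 / 0.136 mL/h | paper |
| tvV, tvV2 | 2.67 / 0.961 mL | paper |
| Clα, Clβ, V exponent | 0.631 / 1.10 / 1 | paper |
| IIV on CL32, residual σ (mRNA) | 52.7% CV, 37.5% | paper |
| IC50 (2-MC / 3-HP / C3/C2) | 21.0 / 37.5 / 32.1 µg/g; Imax 0.999 | paper |
| amenable fractions | 63.7 / 99.8 / 86.9% | paper |
| protein terminal half-life | 168 h | paper (kdeg, kq calibrated) |
| cohort sizes | mice 111 (PD), rats 19, monkeys 16 | paper |
| 3-HP assay LLOQ | 25 µM/L | paper |
| kdeg, kq | 0.0359, 0.00474 1/h | calibrated (see below) |
| ksyn_slope | 0.141 (µg/g)/h per ng/mL | calibrated (see below) |
| ke0 | 0.5 1/h | invented (slight hysteresis) |
| biomarker totals (2-MC, 3-HP, C3/C2) | 20 µM/L, 120 µM/L, 0.8 | invented scale anchors |
| σ for PD observables | 20% | invented |
| body weights | mouse 0.025, rat 0.08, monkey 3, human 70/40/10 kg, ±10% jitter | invented |
| reference weight | 1 kg (typical values read at 1 kg) | convention, config-exposed |

Calibrations solve for unpublished rate constants so that *published
derived quantities* hold exactly: (kdeg, kq) are the degradation-dominant
root giving a 168-h terminal half-life with a fast/slow eigenvalue ratio of
10 (the ratio is not published; it must exceed 3 + 2√2 for this subsystem,
and 10 makes the biexponential decline visible on a weekly grid);
ksyn_slope is set so the typical mouse's steady-state q3W trough protein at
2 mg/kg is 40× the 2-MC IC50, deep in the Imax plateau — encoding the
reported finding that suppression is near-maximal and *maintained* at q3W
doses of 2 mg/kg and above.  The (e0, base) splits reproduce the published
amenable fractions on top of the invented absolute totals.

Sampling grids are invented within the stated observation windows (48 h for
mouse PK; 96 h after the first and last q2W dose for rats and monkeys;
12 weeks for mouse PD, with denser early sampling and a pre-dose baseline
biomarker sample — baseline levels are explicit model parameters, so the
emulated design measures them, as any PD study would).  The mouse PK cohort
defaults to 20 serially sampled animals as a desk-scale stand-in for the
reported 111 (whose per-animal schedule is unstated); a destructive
one-sample-per-animal mode with N=111 is provided.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: assay drift and inter-occasion variability,
dropout, covariates beyond body weight, IIV on parameters other than CL32,
heterogeneity of residual enzyme activity between animals, and any
mechanistic LNP biodistribution.  Parameter recovery here demonstrates that
the estimation machinery is correct under the model's own assumptions, not
that the model is correct for any particular dataset.

## Problem sizes

The bundled round-trip studies use 55 PK subjects (20 mice, 19 rats, 16
monkeys; ~740 observations) and 111 PD mice (~8 800 observations).  The
acceptance script runs the full sequential pipeline on these in roughly
five minutes on a single core; the dose–response summaries use 300
simulated subjects per dose with common random numbers across dose levels.

## Known limitations

* The compartment topology and synthesis law are reconstructions (see
  above); alternative placements of elimination or a saturable synthesis
  term cannot be excluded by the public record.
* FOCEI is deliberately not reimplemented; objective values are not
  comparable to NONMEM/Pumas runs, only the estimates are.
* Standard errors assume a locally quadratic log-likelihood; for weakly
  identified parameters (notably CL32) the %RSE understates asymmetry.
* The human extrapolation carries PD and biomarker parameters across
  species unchanged; every human output is annotated with that assumption.
* Prediction intervals in dose–response summaries reflect between-subject
  variability only, by construction (keeping the suppression ceiling
  exact); residual error can be added in `simulate_regimen`.
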