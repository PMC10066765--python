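"""Round trip: simulate a population study, then recover its parameters.

Generates a small serial-sampling mouse PK cohort with between-subject
variability (log-normal random effect on CL32) and proportional assay
error, then re-estimates three parameters by maximising the exact marginal
likelihood (adaptive Gauss-Hermite quadrature over the random effect).
"""

from mrnapkpd import FitSpec, ModelParameters, default_designs, default_truth, fit
from mrnapkpd.synthetic import generate_study

truth = default_truth()
design = default_designs(n_mouse_pk=16)["mouse-pk"]
data = generate_study(design, truth, seed=42)
print(f"simulated {design.n_subjects} mice, {int((data['EVID'] == 0).sum())} observations")

model = ModelParameters(pk=truth.pk, pop=truth.pop)
spec = FitSpec(
    # start away from the generating values
    free={"tvcl12": 30.0, "omega_cl32": 0.3, "sigma_mrna": 0.25},
    observables=("mrna",),
    compute_se=True,
)
res = fit(data, spec, model)

print(f"converged: {res.converged}, -2LL = {res.neg2ll:.1f}")
print(f"{'parameter':12s} {'estimate':>9s} {'%RSE':>6s} {'truth':>8s}")
for name, true_val in (("tvcl12", 19.7), ("omega_cl32", 0.495), ("sigma_mrna", 0.375)):
    print(f"{name:12s} {res.estimates[name]:9.3f} {res.rse_percent[name]:6.1f} {true_val:8.3f}")
print("\nEstimates sit within a few relative standard errors of the generating")
print("values; a single small cohort cannot pin the IIV tightly (high %RSE).")
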