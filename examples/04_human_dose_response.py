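"""Allometric extrapolation to humans and steady-state dose-response.

Clearances scale with body weight by the fitted power laws (exponent 0.631
for the plasma-to-tissue clearances, 1.10 for the tissue-side ones; volumes
linearly); protein-turnover and biomarker parameters carry over unchanged,
an assumption recorded in the output metadata.  The summary reports percent
biomarker suppression at the steady-state trough under q3W dosing with a
90% population prediction interval.
"""

from mrnapkpd import default_truth, dose_response_summary, extrapolate_params

truth = default_truth()

for wt, label in ((70.0, "adult"), (10.0, "pediatric")):
    sc = extrapolate_params(truth.pk, wt)
    print(f"{label} ({wt:.0f} kg): CL12 = {sc.cl12:.0f} mL/h, V = {sc.v:.0f} mL")

summary = dose_response_summary(
    truth.pk, truth.pd, truth.biomarkers, truth.pop,
    doses=[0.1, 0.3, 0.6, 1.0], wt=70.0,
    interval=504.0, infusion_duration=1.0, n_subjects=300, seed=0,
)
print(f"\nassumption: {summary.metadata['assumption']}")
print("\nq3W dosing, 70 kg adult, steady state (6th interval trough):")
print(f"{'dose':>6s} {'trough PCC':>11s} {'2-MC suppression, median (90% PI) [%]':>40s}")
for dose in summary.doses:
    s = summary.suppression["2mc"][dose]
    print(f"{dose:6.2f} {summary.trough_protein[dose]:11.1f} "
          f"{s['median']:14.1f}  ({s['lo']:5.1f} - {s['hi']:5.1f})")
ceil = summary.ceiling_percent(truth.biomarkers)["2mc"]
print(f"\nThe suppression ceiling is {ceil:.1f}% (amenable fraction x Imax); the")
print("prediction interval narrows as the dose pushes the trough into the plateau.")
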