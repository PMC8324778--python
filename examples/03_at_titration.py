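"""Simulate antithrombin-lowering therapy for one haemophilia A patient.

Runs the 14-level in silico AT titration: extract the patient's
prothrombin conversion curve once, then re-simulate thrombin generation
at decreasing AT fractions and compare against a healthy reference band.
"""

from thrombodyn import (
    CohortSpec,
    at_titration,
    compute_tg_parameters,
    default_rate_constants,
    reference_ranges,
    restoration_report,
)
from thrombodyn.synthetic import generate_cohort

k = default_rate_constants()
cohort = generate_cohort(CohortSpec(seed=1, noise_sd=0.0))
controls = [compute_tg_parameters(s.curve) for s in cohort
            if s.plasma.group == "control"]
ref = reference_ranges(controls)  # mean +/- 2 SD per parameter
patient = next(s for s in cohort if s.plasma.group == "severe")

result = at_titration(patient.curve, patient.plasma, k, reference_range=ref)
report = restoration_report(result, ref)

print(f"patient {patient.curve.label}: FVIII {patient.plasma.fviii:.3f} IU/mL, "
      f"AT {patient.plasma.at_level:.0f} nM")
print(result.params_frame().round(2).to_string(index=False))
print()
print("restoration vs healthy band (peak height):")
for _, row in report.iterrows():
    flag = "within normal range" if row["within_peak_height"] else "below/above range"
    print(f"  AT {row['at_fraction']:5.1%}: peak {row['pct_change_peak_height']:+6.1f}% "
          f"vs baseline -> {flag}")
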