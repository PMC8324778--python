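"""Decompose a TG curve into prothrombin conversion and inhibition.

The inversion recovers the prothrombin conversion rate -dP/dt behind a
measured curve, given the plasma's AT, alpha2-macroglobulin and
fibrinogen levels, and quantifies PCtot, PCmax and the inhibitor
complexes formed.
"""

from thrombodyn import (
    CohortSpec,
    default_rate_constants,
    extract_prothrombin_conversion,
)
from thrombodyn.synthetic import generate_cohort

k = default_rate_constants()
sample = generate_cohort(CohortSpec(seed=3, n_controls=1, n_patients=0))[0]
r = extract_prothrombin_conversion(sample.curve, sample.plasma, k)

print(f"PCtot  {r.pc_tot:6.0f} nM     (total prothrombin converted; truth "
      f"{sample.truth.pc_tot:.0f})")
print(f"PCmax  {r.pc_max:6.1f} nM/min (fastest conversion; truth "
      f"{sample.truth.pc_max:.1f})")
print(f"T-AT   {r.t_at_total:6.0f} nM     (thrombin captured by antithrombin)")
print(f"T-a2M  {r.t_a2m_total:6.1f} nM     (thrombin captured by alpha2-macroglobulin)")
print(f"TDC    {r.tdc:6.3f} /min   (plasma's thrombin decay capacity)")
print(f"conservation residual {100 * r.conservation_residual():+.3f}% "
      "(PCtot vs complexes + residual free thrombin)")
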