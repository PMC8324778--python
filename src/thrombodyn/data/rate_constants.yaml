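# Thrombin inactivation rate constants.
#
# These defaults are documented placeholders at physiologically plausible
# magnitudes; re-calibrate against a reference plasma before quantitative
# use on measured curves. Units: k_at, k_a2m in nM^-1 min^-1; k_ms in
# min^-1; fibrinogen slopes per (g/L), 0 = no fibrinogen dependence.
version: 1
rate_constants:
  k_at: 3.0e-4
  k_a2m: 1.0e-5
  k_ms: 0.01
  fibrinogen_slope_at: 0.0
  fibrinogen_slope_a2m: 0.0
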