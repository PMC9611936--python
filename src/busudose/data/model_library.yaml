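# Published busulfan model constants used as engine defaults.
#
# paci: parametric one-compartment model with allometric body-weight
#   scaling of CL and V (test model, MAP estimation).
# neely: nonparametric one-compartment model parameterized as slope
#   parameters KeS, VS scaled by min(BW, IBW) (reference model,
#   discrete-prior estimation).  Only summary statistics of the support
#   distribution are published; the prior here is reconstructed from them.

paci:
  cl_typical: 2.18           # L/h at the reference weight
  reference_weight: 9.0      # kg
  cl_exponent_low: 1.25      # BW < reference_weight
  cl_exponent_high: 0.76     # BW >= reference_weight
  v_exponent: 0.86           # V (L) = BW^v_exponent
  cl_cv: 0.23                # between-subject CV on CL
  v_cv: 0.22                 # between-subject CV on V
  residual_proportional: 0.11    # fraction of the prediction
  residual_additive: 0.057       # mg/L (57 ng/mL)

neely:
  kes_median: 0.71           # 1/h per kg^-0.25
  kes_min: 0.42
  kes_max: 0.98
  kes_cv: 0.18
  vs_median: 0.72            # L/kg
  vs_min: 0.53
  vs_max: 1.40
  vs_cv: 0.21
  size_exponent_ke: -0.25    # Ke = KeS * size^-0.25
  residual_intercept: 0.02   # mg/L; SD = intercept + slope * Cobs
  residual_slope: 0.1

traub_johnson:
  coefficient: 1.65e-3       # IBW (kg) = coefficient * height(cm)^2
  height_bounds: [40.0, 200.0]   # plausibility range; outside -> warning
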