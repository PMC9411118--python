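# Published regression coefficients used as forward-predictor data.
# All trait regressions are on natural-log-transformed variables.
# Mass basis: rates in nmol g-1 s-1, nutrients in mg g-1.
# Area basis: rates in umol m-2 s-1, nutrients in g m-2.
version: 1

# Forward Vcmax/Jmax = f(N, P) predictor sets.
predictor_sets:
  # The set used in the canopy-model experiment ("as modelled"): main effects
  # of ln P and ln N only, mass and area bases fitted independently.
  methods:
    mass:
      Vcmax:  {intercept: 4.4490, coef_lnP: 0.3472, coef_lnN: 0.49078}
      Jmax:   {intercept: 5.4944, coef_lnP: 0.3735, coef_lnN: 0.4144}
    area:
      Vcmax:  {intercept: 4.308, coef_lnP: 0.298, coef_lnN: 0.197}
      Jmax:   {intercept: 5.139, coef_lnP: 0.325, coef_lnN: 0.112}
  # Full-dataset multiple-regression set including the N x P interaction
  # (mass basis only; recommended descriptive model).
  table2:
    mass:
      Vcmax:  {intercept: 4.636, coef_lnN: 0.453, coef_lnP: -0.546, coef_lnN_lnP: 0.321, r2: 0.42}
      Jmax:   {intercept: 5.535, coef_lnN: 0.388, coef_lnP: -0.436, coef_lnN_lnP: 0.295, r2: 0.47}
      Amass:  {intercept: 2.998, coef_lnN: 0.513, coef_lnP: -0.547, coef_lnN_lnP: 0.294, r2: 0.35}

# Leaf dry mass per area (g m-2) as a function of N_mass and P_mass (mg g-1),
# natural-log scale with N x P interaction.
ma_model:
  intercept: 6.484
  coef_lnN: -0.598
  coef_lnP: 0.461
  coef_lnN_lnP: -0.214
  r2: 0.51

# Single-factor log-log OLS lines (mass basis) by leaf-P class; the P class
# threshold is P_mass = 0.92 mg g-1 (low: P < threshold; moderate: P >= it).
single_factor:
  p_threshold: 0.92
  Anet_vs_N:
    moderate: {slope: 0.779, intercept: 2.323, r2: 0.16, df: 231}
    low:      {slope: 0.369, intercept: 3.242, r2: 0.19, df: 212}
    all:      {slope: 0.741, intercept: 2.350, r2: 0.28, df: 445}
  Vcmax_vs_N:
    moderate: {slope: 0.736, intercept: 3.929, r2: 0.26, df: 231}
    low:      {slope: 0.367, intercept: 4.689, r2: 0.08, df: 212}
    all:      {slope: 0.751, intercept: 3.783, r2: 0.30, df: 445}
  Jmax_vs_N:
    moderate: {slope: 0.671, intercept: 4.825, r2: 0.23, df: 231}
    low:      {slope: 0.382, intercept: 5.366, r2: 0.10, df: 212}
    # The published all-P row is inconsistent in magnitude with the class
    # rows; shipped for completeness, excluded from generator defaults.
    all:      {slope: 0.310, intercept: 8.564, r2: 0.44, df: 444, suspect: true}
  Vcmax_vs_P:
    all:      {slope: 0.515, intercept: 5.983, r2: 0.34, df: 445}
  Jmax_vs_P:
    all:      {slope: 0.527, intercept: 6.692, r2: 0.40, df: 445}

# Linear (not log) Jmax-Vcmax lines for the two end-member P_mass classes
# (area basis, 25 degC), Jmax = intercept + slope * Vcmax.
jv_lines:
  low:  {intercept: 17.5, slope: 1.52, r2: 0.82, n: 111}
  high: {intercept: 12.8, slope: 1.79, r2: 0.71, n: 112}

# Sigmoidal plant P-acquisition scalar of the leaf N:P mass ratio:
# f(N:P) = 1 / (1 + exp(-(N:P)/divisor + offset)); midpoint at N:P = 20.
p_acquisition:
  divisor: 2.0
  offset: 10.0

# Unlimited-P diagnostic: leaf P_mass ceiling at the minimum N:P mass ratio.
min_n_to_p: 5.0

# Squared correlation between ln N_mass and ln P_mass across species-site
# means, used to calibrate the synthetic trait generator.
lnN_lnP_r2: 0.39
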