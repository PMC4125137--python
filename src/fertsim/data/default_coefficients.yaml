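# Default coefficient set for the two-day conception-hazard model.
# Point estimates from a multilevel discrete-time survival analysis of
# 1,247,677 risk periods (21,913 lactations, 12,515 cows, 39 UK dairy herds).
# Category coefficients are odds ratios relative to the reference level
# (parity 1, year <=2002, season Jan-Mar, no lameness in window); windows
# not retained in the final model carry odds ratio 1.0.
intercept: -40.1
ln_dim: 15.4
ln_dim_sq: -1.62
odds_ratios:
  parity:
    "2": 1.056
    "3": 0.978
    "4": 0.948
    ">4": 0.761
  year:
    "2003": 1.000
    "2004": 0.901
    "2005": 0.928
    "2006": 0.858
    "2007-8": 0.897
  season:
    Apr-Jun: 0.897
    Jul-Sep: 0.736
    Oct-Dec: 0.997
  yield_per_1000l: 0.917
  lameness:
    lame_71_100_before: 1.0
    lame_43_70_before: 0.850
    lame_15_42_before: 1.0
    lame_within_14: 0.760
    lame_15_42_after: 1.0
    lame_43_70_after: 0.880
    lame_71_100_after: 0.861
# Random-effect variances are not part of the published estimates; these are
# the package's generator defaults (modest cow/herd clustering).
variance:
  cow: 0.09
  herd: 0.04
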