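# Default growth-standard coefficient set ("hadlock").
#
# Hadlock-type gestational-age-from-biometry polynomials (GA in weeks as a
# polynomial in the measurement in cm), a Hadlock three-parameter log10 EFW
# formula, and a log-scale EFW-for-GA reference.  Ultrasound machines ship
# their own (often proprietary) curve tables; this set is a clearly labelled
# default — swap in a different YAML to match a specific scanner.
name: hadlock
planes:
  HC:
    # GA(weeks) = c0 + c1*x + c2*x^2 + c3*x^3, x = head circumference in cm
    ga_weeks_from_cm: [8.96, 0.540, 0.0, 0.0003]
    valid_ga_days: [84, 294]
    bracket_cm: [0.5, 80.0]
  AC:
    ga_weeks_from_cm: [8.14, 0.753, 0.0036]
    valid_ga_days: [84, 294]
    bracket_cm: [0.5, 80.0]
  FL:
    ga_weeks_from_cm: [10.35, 2.460, 0.170]
    valid_ga_days: [84, 294]
    bracket_cm: [0.1, 30.0]
efw:
  # log10(EFW g) = intercept + hc*HC + ac*AC + fl*FL + ac_fl*AC*FL, all in cm
  type: hadlock3_log10_cm
  intercept: 1.326
  hc: 0.0107
  ac: 0.0438
  fl: 0.158
  ac_fl: -0.00326
  # physiologic domain (mm) inside which monotonicity in each argument holds
  domain_mm:
    HC: [80.0, 450.0]
    AC: [80.0, 480.0]
    FL: [15.0, 110.0]
efw_for_ga:
  # ln(median EFW g) = a + b*GAw + c*GAw^2 ; constant SD on the log scale
  mean_log_coeffs: [0.578, 0.332, -0.00354]
  log_sd: 0.127
  valid_ga_days: [70, 294]
centile_cutoffs:
  sga: 10.0
  lga: 90.0
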