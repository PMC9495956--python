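# Yearly atmospheric CO2 concentration curves per SSP scenario, valid 1981-2070.
#
# Each scenario is a sum of terms from a small term library:
#   constant:     value
#   linear:       coef * y
#   power:        coef * y**exponent
#   rational:     num / (c0 + c1 * y)
#   shifted_poly: coef * (y - center)**degree
#
# The shifted-polynomial and linear terms are transcribed from the published
# fitted curves (exponents such as "2.4959104" read as 2.4959e-4).  The
# leading non-polynomial terms of the published curves are typographically
# ambiguous; they are RECONSTRUCTED here as a single constant per scenario,
# calibrated so that every curve passes through 340.0 ppm in 1981 (the
# observed global-mean concentration for that year).  See docs/methods.md.
valid_years: [1981, 2070]
envelope_ppm: [300.0, 1200.0]
scenarios:
  SSP126:
    - {type: constant, value: 170.056647}
    - {type: shifted_poly, coef: 4.5948, center: 1961, degree: 1}
    - {type: shifted_poly, coef: -0.023987, center: 1977, degree: 2}
    - {type: shifted_poly, coef: -2.4959e-4, center: 2054, degree: 3}
    - {type: shifted_poly, coef: -6.5721e-7, center: 2054, degree: 4}
  SSP245:
    - {type: constant, value: 67.007963}
    - {type: shifted_poly, coef: 0.028057, center: 1900, degree: 2}
    - {type: shifted_poly, coef: 2.6827e-4, center: 1960, degree: 3}
    - {type: shifted_poly, coef: -9.2751e-7, center: 1910, degree: 4}
    - {type: shifted_poly, coef: -2.2448, center: 2030, degree: 1}
  SSP370:
    - {type: constant, value: 157.167301}
    - {type: shifted_poly, coef: 4.752e-5, center: 143.55, degree: 2}
    - {type: shifted_poly, coef: 1.037e-4, center: 1908, degree: 3}
    - {type: shifted_poly, coef: -5.9113e-8, center: 1849, degree: 4}
  SSP585:
    - {type: constant, value: -659.168771}
    - {type: shifted_poly, coef: 2.4712e-4, center: -15, degree: 2}
    - {type: shifted_poly, coef: 1.9299e-5, center: 1937, degree: 3}
    - {type: shifted_poly, coef: 5.1137e-7, center: 1910, degree: 4}
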