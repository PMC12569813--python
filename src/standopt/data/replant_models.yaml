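# Replant initialization model bank, version 1.
#
# Per species and variable (H tree height m, CW crown width m, CL crown
# length m): a functional form in DBH (cm), its parameters, and the
# published stand factor — the expected value at the replant
# initialization diameter of 5 cm.  Where the parameters do not reproduce
# the stand factor at 2 decimals, the loader pins the DBH=5 output to the
# stand factor through an additive calibration offset (see growth_models).
#
# Form catalogue:
#   chapman_richards      a*(1-exp(-b*D))^c
#   power                 a*D^b
#   logistic              a/(1+b*exp(-c*D))
#   reciprocal            1/(a+b/D)          (reciprocal-of-DBH height curve)
#   exponential_decay     a*exp(-b/D^c)
#   quadratic             a+b*D+c*D^2
#   log_linear            exp(a+b*ln(D))
#   cubic_in_dbh          a+b*D^2+c*D^3
#   shifted_exponential   a*exp(b-c/(D+1))+d
version: 1
species:
  pinus_yunnanensis:
    H:  {form: chapman_richards, params: {a: 16.7289, b: 0.0871, c: 1.1212}, stand_factor: 5.20}
    CW: {form: power, params: {a: 0.5652, b: 0.7023}, stand_factor: 1.74}
    CL: {form: power, params: {a: 0.3646, b: 0.7984}, stand_factor: 1.32}
  pinus_armandii:
    H:  {form: chapman_richards, params: {a: 17.0986, b: 0.0816, c: 0.9258}, stand_factor: 5.19}
    CW: {form: logistic, params: {a: 4.2420, b: 2.2677, c: 0.0523}, stand_factor: 1.54}
    CL: {form: chapman_richards, params: {a: 41.0291, b: 0.0289, c: 0.4971}, stand_factor: 2.56}
  quercus_acutissima:
    H:  {form: shifted_exponential, params: {a: 1.0822, b: 3.2453, c: 17.2914, d: 3.5632}, stand_factor: 5.12}
    CW: {form: cubic_in_dbh, params: {a: 0.2574, b: 0.2442, c: -0.0022}, stand_factor: 1.82}
    CL: {form: power, params: {a: 0.4833, b: 0.6892}, stand_factor: 1.47}
  betula_alnoides:
    H:  {form: reciprocal, params: {a: 0.0211, b: 0.6850}, stand_factor: 6.33}
    CW: {form: logistic, params: {a: 3.0360, b: 0.8446, c: 0.1345}, stand_factor: 2.12}
    CL: {form: power, params: {a: 2.0317, b: 0.2375}, stand_factor: 2.98}
  vaccinium_bracteatum:
    H:  {form: exponential_decay, params: {a: 2.2004, b: 0.5011, c: 4.9997}, stand_factor: 2.20}
    CW: {form: logistic, params: {a: 2.9716, b: 1.0269, c: -0.0314}, stand_factor: 1.35}
    CL: {form: logistic, params: {a: 1.0123, b: 0.7829, c: 4.0326}, stand_factor: 1.01}
  camellia_sinensis:
    H:  {form: chapman_richards, params: {a: 10.0002, b: 0.2114, c: 1.9997}, stand_factor: 4.26}
    CW: {form: logistic, params: {a: 1.9389, b: 0.5366, c: 0.1097}, stand_factor: 1.48}
    CL: {form: power, params: {a: 0.9009, b: 0.3250}, stand_factor: 1.55}
  ternstroemia_gymnanthera:
    H:  {form: quadratic, params: {a: 2.9963, b: 0.9818, c: -0.1110}, stand_factor: 5.13}
    CW: {form: log_linear, params: {a: -0.1710, b: 0.2247}, stand_factor: 1.21}
    CL: {form: chapman_richards, params: {a: 1.9964, b: 0.1762, c: 1.0005}, stand_factor: 1.17}
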