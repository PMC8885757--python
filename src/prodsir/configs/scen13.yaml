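id: scen13
description: Estimated extra observation variance (time-varying catchability)
anchor_year: 2019
n_c: 72
catch_series: both
include_in_average: true
priors:
  tau2: {dist: lognormal, meanlog: -1.6094379124341003, sdlog: 0.5}
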