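id: scen2
description: Lognormal prior on the maximum rate of increase (CV 30%)
anchor_year: 2019
n_c: 72
catch_series: both
include_in_average: true
priors:
  r_max: {dist: lognormal, meanlog: -2.67, sdlog: 0.3}
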