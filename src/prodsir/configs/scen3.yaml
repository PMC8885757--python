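id: scen3
description: Truncated lognormal prior on the maximum rate of increase
anchor_year: 2019
n_c: 72
catch_series: both
include_in_average: true
priors:
  r_max: {dist: truncated-lognormal, meanlog: -2.67, sdlog: 0.5, low: 0.02, high: 0.11}
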