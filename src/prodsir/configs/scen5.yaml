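id: scen5
description: Process-variance upper bound at 2x the lower bound
anchor_year: 2019
n_c: 72
catch_series: both
include_in_average: false
priors:
  sigma2: {dist: uniform, low: 6.5e-5, high: 1.3e-4}
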