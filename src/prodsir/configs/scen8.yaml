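id: scen8
description: Low catch series only
anchor_year: 2019
n_c: 72
catch_series: low-only
include_in_average: false
priors: {}
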