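id: base
description: Base case priors and data configuration
anchor_year: 2019
n_c: 72
catch_series: both
include_in_average: true
priors: {}
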