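id: scen11
description: Minimum-abundance floor of 75 (25 haplotypes)
anchor_year: 2019
n_c: 75
catch_series: both
include_in_average: true
priors: {}
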