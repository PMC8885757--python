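id: scen6
description: Recent-abundance prior anchored at 2004
anchor_year: 2004
n_c: 72
catch_series: both
include_in_average: true
priors: {}
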