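id: scen7
description: No struck-and-lost correction
anchor_year: 2019
n_c: 72
catch_series: no-slr
include_in_average: false
priors: {}
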