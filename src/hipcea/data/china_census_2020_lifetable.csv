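# Annual probability of death from all (other) causes, by single year of age.
# Transcribed from age-specific mortality rates of the China Population Census
# 2020 (both sexes combined, rounded). Census-based old-age mortality in 2020
# is known to run low relative to UN estimates; these values are shipped as a
# convenience fixture only, and every model entry point accepts a user-supplied
# life table in the same two-column format.
age,qx
80,0.0388
81,0.0434
82,0.0486
83,0.0545
84,0.0611
85,0.0685
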