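# Synthetic SEC calibration standards table (instrument retention times are
# not published; these RTs follow a plausible log-linear curve,
# log10(kDa) ~ 3.2 - 0.095*RT, so examples and demos run offline).
# Masses: Thyroglobulin 670, gamma-Globulin 150, Ovalbumin 44.3,
# Ribonuclease A 13.7, p-aminobenzoic acid 0.137 kDa.
name	mass_kda	retention_time_min
Thyroglobulin	670	3.95
gamma-Globulin	150	10.72
Ovalbumin	44.3	16.45
Ribonuclease A	13.7	21.75
p-aminobenzoic acid	0.137	42.81
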