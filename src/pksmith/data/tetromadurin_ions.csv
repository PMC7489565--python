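# Observed positive-mode LC-MS ion list for tetromadurin (C42H64O12) from the
# producing Actinomadura strain (unit-resolution ion trap; literature-reported
# values, intensities not reported).
# Note: the water-loss value below is internally inconsistent with the
# [M+H]+ ion (22.0 Da apart instead of ~18.0); it is stored as printed.
mz,intensity,label
783.81,1.0,[M+Na]+
778.82,1.0,[M+NH4]+
761.84,1.0,[M+H]+
739.84,1.0,[M+H-H2O]+
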