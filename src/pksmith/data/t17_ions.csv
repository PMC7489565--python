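# Observed positive-mode LC-MS ion list for T-17 (C42H64O11), the shunt
# metabolite of the PyrE3-like-cyclase (mad10) deletion strain (literature-reported
# values, intensities not reported).
mz,intensity,label
767.69,1.0,[M+Na]+
762.58,1.0,[M+NH4]+
745.63,1.0,[M+H]+
727.70,1.0,[M+H-H2O]+
709.79,1.0,[M+H-2H2O]+
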