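name,multimer,mass_delta,charge,polarity
[M+H]+,1,1.00727646688,1,positive
[M+Na]+,1,22.98922070,1,positive
[M+NH4]+,1,18.03382555,1,positive
[M+K]+,1,38.96315790,1,positive
[2M+H]+,2,1.00727646688,1,positive
[M+H-H2O]+,1,-17.00328823,1,positive
[M-H]-,1,-1.00727646688,-1,negative
[M+HCOO]-,1,44.99820284,-1,negative
[M+Cl]-,1,34.96940126,-1,negative
[2M-H]-,2,-1.00727646688,-1,negative
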