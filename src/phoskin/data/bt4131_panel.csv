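variant,substrate,kcat_km,sd,measured
WT,Glc6P,30.98,1.75,True
WT,Fru6P,10.08,1.67,True
WT,GlcN6P,2.08,0.48,True
WT,GlcNAc6P,13.28,1.83,True
M1,Glc6P,11.32,2.28,True
M1,Fru6P,2.71,0.98,True
M1,GlcN6P,19,3.7,True
M1,GlcNAc6P,31.88,1.78,True
M2,Glc6P,46.38,7.36,True
M2,Fru6P,7.25,1.41,True
M2,GlcN6P,26.39,1.49,True
M2,GlcNAc6P,67.48,4.95,True
M3,Glc6P,12.2,3.96,True
M3,Fru6P,1.47,0.34,True
M3,GlcN6P,2.09,0.48,True
M3,GlcNAc6P,74.72,5.64,True
M4,Glc6P,12.58,2.25,True
M4,Fru6P,,,False
M4,GlcN6P,,,False
M4,GlcNAc6P,126.27,7.84,True
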