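PANOPTOSIS	27-gene PANoptosis signature (pyroptosis/apoptosis/necroptosis sensors, adaptors, effectors)	ADAR	AIM2	MEFV	NLRC4	NLRP1	NLRP3	NLRP9	TNFRSF1A	ZBP1	FADD	PYCARD	CASP1	CASP10	CASP12	CASP2	CASP3	CASP4	CASP5	CASP6	CASP7	CASP8	DFNA5	GSDMD	MLKL	RIPK1	RIPK3	TNF
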