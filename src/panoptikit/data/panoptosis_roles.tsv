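gene	role
ADAR	sensor/upstream regulator
AIM2	sensor/upstream regulator
MEFV	sensor/upstream regulator
NLRC4	sensor/upstream regulator
NLRP1	sensor/upstream regulator
NLRP3	sensor/upstream regulator
NLRP9	sensor/upstream regulator
TNFRSF1A	sensor/upstream regulator
ZBP1	sensor/upstream regulator
FADD	adaptor
PYCARD	adaptor
CASP1	effector
CASP10	effector
CASP12	effector
CASP2	effector
CASP3	effector
CASP4	effector
CASP5	effector
CASP6	effector
CASP7	effector
CASP8	effector
DFNA5	effector
GSDMD	effector
MLKL	effector
RIPK1	effector
RIPK3	effector
TNF	effector
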