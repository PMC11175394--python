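diagnosis_province,EC,FS,GAU,KZN,LIM,MPU,NW,NC,WC
EC,4202,17,92,94,8,15,25,25,126
FS,19,4250,392,101,45,110,127,53,11
GAU,260,579,17682,4104,853,2840,1131,85,126
KZN,51,16,391,3806,14,183,11,1,17
LIM,3,17,322,26,3856,174,60,3,4
MPU,17,39,946,536,125,4634,31,8,8
NW,23,52,226,28,22,35,3037,19,8
NC,18,37,43,7,1,8,51,1251,35
WC,608,166,209,64,14,43,97,170,6200
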