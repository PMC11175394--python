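characteristic,level,outside,within
total,all,16364,48920
gender,Female,12110,34203
gender,Male,4254,14708
ethnicity,Black,15088,42407
ethnicity,Coloured,484,2732
ethnicity,White,645,2399
ethnicity,Asian,69,315
black_vs_nonblack,Black,15088,42407
black_vs_nonblack,non-Black,1198,5446
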