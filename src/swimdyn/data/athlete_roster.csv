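athlete,gender,birth_year,height_m,weight_kg,level
S1,Male,1981,1.88,94,International swimming master
S2,Male,1983,1.93,90,Swimming master
S3,Male,1986,1.76,71.5,Swimming master
S4,Male,1986,1.85,76,Swimming level 1
S5,Male,1985,1.83,75,Swimming master
S6,Male,1987,1.94,75,Swimming master
S7,Male,1988,1.71,71,Swimming master
S8,Male,1982,1.77,71,Athletics level 2
S9,Male,1959,1.78,70,Swimming level 3
S10,Male,1963,1.75,75,Athletics level 1
S11,Male,1969,1.74,59,Gymnastics level 2
S12,Female,1984,1.71,63,Swimming level 1
S13,Male,1985,1.78,65,Swimming level 1
S14,Female,1978,1.73,68,Swimming master
S15,Male,1981,1.80,70,Swimming master
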