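speed,15,20,25,30
2.1,2.40,2.39,2.37,2.34
2.3,2.29,2.29,2.27,2.24
3.0,2.04,2.04,2.02,1.99
4.0,1.84,1.82,1.81,1.78
5.0,1.71,1.70,1.69,1.65
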