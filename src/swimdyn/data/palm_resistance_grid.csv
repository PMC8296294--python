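speed,15,20,25,30
2.1,79.61,79.46,78.83,77.83
2.3,91.48,91.26,90.56,89.30
3.0,138.67,138.06,137.14,134.72
4.0,221.30,219.99,218.77,214.13
5.0,321.91,319.71,318.16,310.70
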