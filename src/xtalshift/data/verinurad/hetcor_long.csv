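f1_ppm,f2_ppm
49.1,1.01
49.1,1.12
175.9,15.91
109.7,6.63
134.2,9.09
140.8,8.07
134.2,8.07
132.5,8.07
132.5,7.25
131.4,7.86
152.1,7.84
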