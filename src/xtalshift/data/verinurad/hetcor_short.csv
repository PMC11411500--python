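f1_ppm,f2_ppm
148.5,9.09
145.9,8.67
129.2,8.07
132.8,6.63
124.0,7.86
129.1,7.19
127.4,6.1
127.6,7.25
122.2,7.84
27.0,1.01
25.1,1.12
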