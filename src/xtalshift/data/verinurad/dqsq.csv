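f1_ppm,f2_ppm
25.0,9.09
25.0,15.91
14.7,6.63
14.7,8.07
13.26,6.63
15.86,8.67
15.86,7.19
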