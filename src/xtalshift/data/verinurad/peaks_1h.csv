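id,shift_ppm
H01,15.91
H02,9.09
H03,8.67
H04,8.07
H05,7.86
H06,7.84
H07,7.25
H08,7.19
H09,6.63
H10,6.1
H11,1.12
H12,1.01
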