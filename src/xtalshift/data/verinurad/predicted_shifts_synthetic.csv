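site_label,value,kind,sd
C2,149.5090,shift,
C3,136.2563,shift,
C4,152.2749,shift,
C5,122.0000,shift,
C6,145.2127,shift,
C7,139.1625,shift,
C8,122.8948,shift,
C9,130.3377,shift,
C10,115.2524,shift,
C11,136.5369,shift,
C12,123.5000,shift,
C13,132.9783,shift,
C14,124.6227,shift,
C15,125.1782,shift,
C16,136.7244,shift,
C18,50.9666,shift,
C19,27.3535,shift,
C20,123.1941,shift,
C22,23.0281,shift,
C23,175.5427,shift,
H2,9.5451,shift,
H5,7.8987,shift,
H6,8.8809,shift,
H8,7.1661,shift,
H9,6.5793,shift,
H12,7.7505,shift,
H13,8.1020,shift,
H14,6.0350,shift,
H15,7.7324,shift,
H19,0.4654,shift,
H22,1.3077,shift,
H24,15.6817,shift,
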