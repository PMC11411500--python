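site_label,value,kind,sd
C2,148.5,shift,
C3,134.2,shift,
C4,152.1,shift,
C5,122.0,shift,
C6,145.9,shift,
C7,140.8,shift,
C8,129.2,shift,
C9,132.8,shift,
C10,109.7,shift,
C11,131.4,shift,
C12,123.5,shift,
C13,129.1,shift,
C14,127.4,shift,
C15,127.6,shift,
C16,132.5,shift,
C18,49.1,shift,
C19,27.0,shift,
C20,118.1,shift,
C22,25.1,shift,
C23,175.9,shift,
H2,9.09,shift,
H5,7.84,shift,
H6,8.67,shift,
H8,8.07,shift,
H9,6.63,shift,
H12,7.86,shift,
H13,7.19,shift,
H14,6.1,shift,
H15,7.25,shift,
H19,1.01,shift,
H22,1.12,shift,
H24,15.91,shift,
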