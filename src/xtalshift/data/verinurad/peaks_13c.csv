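id,shift_ppm
C01,175.9
C02,152.1
C03,148.5
C04,145.9
C05,140.8
C06,134.2
C07,132.8
C08,132.5
C09,131.4
C10,129.2
C11,129.1
C12,127.6
C13,127.4
C14,124.0
C15,122.2
C16,118.1
C17,109.7
C18,49.1
C19,27.0
C20,25.1
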