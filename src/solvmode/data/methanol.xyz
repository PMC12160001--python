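6
methanol template (idealized geometry, r_CO = 1.43 A, r_OH = 0.96 A, r_CH = 1.09 A)
C 0.000000 0.000000 0.000000
O 1.430000 0.000000 0.000000
H 1.734608 0.910368 0.000000
H -0.363842 -1.027434 0.000000
H -0.363842 0.513717 0.889784
H -0.363842 0.513717 -0.889784
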