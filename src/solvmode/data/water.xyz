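3
water template (gas-phase geometry, r_OH = 0.9572 A, HOH = 104.52 deg)
O 0.000000 0.000000 0.000000
H 0.957200 0.000000 0.000000
H -0.240045 0.926627 0.000000
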