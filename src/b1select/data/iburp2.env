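# I-BURP-2 band-selective inversion envelope, Fourier-series coefficients
# transcribed from Geen & Freeman, J. Magn. Reson. 93, 93-141 (1991).
# B(s) = a0 + sum_n [ a_n cos(2 pi n s) + b_n sin(2 pi n s) ],  s in [0, 1).
# "a" lists a0 a1 ... ; "b" lists b1 b2 ... (no constant sine term).
name iburp2
a 0.5 0.81 0.07 -1.25 -0.24 0.07 0.11 0.05 -0.02 -0.03 -0.02 0.00
b -0.68 -1.03 0.16 0.30 0.03 -0.06 -0.04 0.01 0.01 0.00 0.00
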