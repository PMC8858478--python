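# Three two-patient samples at consecutive ISS ranks demonstrating that
# the ISS variance inflates with the (uneven) gaps of the ISS scale:
# ranks 28/29, 32/33 and 34/35.
sample,A1,B1,C1,A2,B2,C2
A,5,2,2,5,3,0
B,5,3,2,5,4,0
C,5,3,3,5,4,1
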