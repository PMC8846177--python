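# Junction bend-test outcomes 30 days after grafting, reconstructed from the
# published breakage percentages (0%, 6%, 75%, 92% for T:T, P:P, P:T, T:P)
# and group sizes within the reported n = 12-18 range; this is the unique
# reconstruction in that range whose counts round back to every printed
# percentage and whose Fisher exact p matches the printed value (5.967e-11).
outcome,T:T,P:P,P:T,T:P
broke,0,1,9,11
intact,18,17,3,1
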