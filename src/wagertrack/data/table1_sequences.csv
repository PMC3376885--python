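id,participant_n,sequence,printed_G
g25,11,4-2-3-2-1-2-1-2-4-1-3-2-1-4-1-3-1-3-2-4-1-3-1-3-1-4-2-4-3-4-2-4-1-3-1-4-2-3-2-4-1-4-2-3-4-3-2-3,0.25
g40,14,1-2-3-1-3-1-2-1-2-1-3-4-3-4-1-2-4-2-4-2-4-3-1-2-4-3-4-2-4-3-4-3-1-2-3-4-2-1-3-4-2-1-3-1-3-4-2-1,0.40
g44,16,2-1-4-3-4-3-2-4-1-2-3-2-1-2-1-4-3-4-3-2-3-2-3-2-1-3-2-1-4-1-4-1-4-3-4-1-2-1-4-1-4-3-2-3-2-3-4-1,0.44
g55,11,4-2-3-4-2-1-3-1-3-1-3-1-3-4-2-4-2-4-2-1-3-1-3-1-3-4-2-3-4-2-1-3-1-3-4-1-2-1-2-4-2-4-2-1-3-4-2-4,0.55
g68,11,4-3-4-3-4-3-2-1-4-3-2-1-4-3-2-1-4-3-2-1-4-3-2-1-3-2-1-4-3-2-1-3-2-1-2-1-4-3-2-1-2-1-4-3-4-2-1-4,0.68
g76,13,3-2-3-2-4-1-3-2-4-1-4-1-3-2-3-2-3-2-4-1-3-2-4-1-3-2-3-2-4-1-3-2-4-1-4-1-3-2-4-1-4-1-4-1-4-1-3-2,0.76
g79,10,2-3-1-4-1-4-1-4-2-3-1-4-2-3-1-4-2-3-1-4-2-3-1-4-2-3-2-3-2-3-2-3-1-4-1-4-2-3-1-4-2-3-1-4-2-3-1-4,0.79
g89,15,2-3-4-1-2-3-4-1-2-3-2-3-4-1-2-3-4-1-2-3-4-1-2-3-4-1-2-3-4-1-4-1-2-3-4-1-2-3-4-1-2-3-4-1-2-3-4-1,0.89
g100a,15,2-1-3-4-2-1-3-4-2-1-3-4-2-1-3-4-2-1-3-4-2-1-3-4-2-1-3-4-2-1-3-4-2-1-3-4-2-1-3-4-2-1-3-4-2-1-3-4,1.0
g100b,14,1-2-4-3-1-2-4-3-1-2-4-3-1-2-4-3-1-2-4-3-1-2-4-3-1-2-4-3-1-2-4-3-1-2-4-3-1-2-4-3-1-2-4-3-1-2-4-3,1.0
g100c,11,4-3-2-1-4-3-2-1-4-3-2-1-4-3-2-1-4-3-2-1-4-3-2-1-4-3-2-1-4-3-2-1-4-3-2-1-4-3-2-1-4-3-2-1-4-3-2-1,1.0
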