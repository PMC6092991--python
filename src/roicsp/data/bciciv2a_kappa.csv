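subject,sensor,source,winner_fbcsp
A01T,0.48,0.50,0.76
A02T,0.27,0.34,0.47
A03T,0.57,0.61,0.83
A04T,0.19,0.30,0.48
A05T,0.17,0.30,0.60
A06T,0.17,0.26,0.34
A07T,0.42,0.56,0.86
A08T,0.56,0.63,0.80
A09T,0.64,0.66,0.78
Mean,0.39,0.46,0.65
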