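subject,Left,Right,Foot,Tongue
A01T,49.03,70.00,47.92,75.56
A02T,38.75,41.11,61.81,42.22
A03T,80.14,80.83,50.14,60.83
A04T,34.86,37.64,37.92,46.53
A05T,43.33,48.33,25.83,32.08
A06T,35.42,38.33,50.56,27.64
A07T,68.61,57.08,44.03,56.25
A08T,73.47,61.67,65.28,69.31
A09T,81.67,68.89,67.64,78.47
Mean,56.14,55.99,50.12,54.32
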