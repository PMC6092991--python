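subject,Left,Right,Foot,Tongue
A01T,55.97,70.56,52.64,70.69
A02T,49.72,38.33,67.08,50.14
A03T,81.25,81.39,57.92,63.06
A04T,49.44,38.61,48.47,46.53
A05T,71.39,59.17,25.00,37.92
A06T,47.36,44.58,59.03,24.44
A07T,88.47,72.50,45.56,60.56
A08T,77.22,75.14,60.14,76.11
A09T,84.58,70.28,65.00,76.94
Mean,67.27,61.17,53.43,56.27
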