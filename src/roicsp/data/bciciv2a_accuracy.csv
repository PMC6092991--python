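subject,sensor,source
A01T,61.0,62.4
A02T,45.8,51.3
A03T,68.2,70.9
A04T,39.4,46.3
A05T,38.0,47.6
A06T,37.7,43.7
A07T,56.3,67.2
A08T,67.3,71.9
A09T,73.4,74.5
Mean,54.1,59.7
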