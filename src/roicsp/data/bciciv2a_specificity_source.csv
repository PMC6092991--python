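subject,Left,Right,Foot,Tongue
A01T,86.20,85.88,88.80,89.07
A02T,76.90,84.07,88.33,85.79
A03T,89.63,93.29,89.63,88.66
A04T,75.46,84.07,84.40,83.75
A05T,79.12,80.37,86.76,84.91
A06T,78.15,78.75,82.08,86.16
A07T,88.15,89.17,87.69,90.69
A08T,93.70,90.51,86.99,91.67
A09T,92.27,91.85,88.52,92.96
Mean,84.40,86.44,87.02,88.18
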