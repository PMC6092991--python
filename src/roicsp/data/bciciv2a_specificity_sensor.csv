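subject,Left,Right,Foot,Tongue
A01T,85.28,84.86,88.33,89.03
A02T,79.63,80.83,87.64,79.86
A03T,91.67,93.47,86.76,85.42
A04T,78.94,77.31,82.59,80.14
A05T,79.40,80.83,79.03,77.27
A06T,80.93,77.96,79.91,78.52
A07T,87.04,85.14,82.50,87.31
A08T,94.21,87.55,83.98,90.83
A09T,93.47,92.78,86.67,92.64
Mean,85.62,84.53,84.16,84.56
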