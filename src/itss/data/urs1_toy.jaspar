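>URS1_toy URS1
A [  5  4  3  4  5  3  4  5  5 ]
C [  5 88  4  4 85  4  3 85  5 ]
G [  5  4 90 88  5 90 90  5  5 ]
T [ 85  4  3  4  5  3  3  5 85 ]
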