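>MSE_toy MSE
A [  5 25  5 45  5 85 85 85 85 45  5 85 ]
C [  5 25 85  5 85  5  5  5  5  5  5  5 ]
G [ 85 25  5 45  5  5  5  5  5  5  5  5 ]
T [  5 25  5  5  5  5  5  5  5 45 85  5 ]
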