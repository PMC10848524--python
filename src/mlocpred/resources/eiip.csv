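base,eiip
A,0.1260
C,0.1340
G,0.0806
T,0.1335
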