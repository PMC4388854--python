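[The other displayed tree of fig7_N2prime.]
(a:0.5,(c:0.8,b:0.8)v:0.3)p:0.2;
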