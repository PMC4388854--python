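[Weighted tree (a,(b,c)) with outgroup o; displayed by fig2_N2.]
(o:1,(a:0.5,(c:0.8,b:0.8)v:0.3)p:0.2)r;
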