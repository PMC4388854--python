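[Outgroup-rooted network in which taxon c is the hybrid.]
(o:1,((a:0.7,(b:0.5,(c:0.6)#H1:0.4)s:0.2)v:0.3,#H1:0.3)p:0.2)r;
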