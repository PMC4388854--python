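[Outgroup-rooted network in which taxon b is the hybrid: a reticulation cycle with side exits to a and c and bottom exit to b.]
(o:1,((a:0.5,(b:0.4)#H1:0.2)p:0.3,(c:0.6,#H1:0.3)q:0.4)m:0.2)r;
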