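[Outgroup-rooted network in which taxon a is the hybrid; the only one of fig2_N1/N2/N3 that can display the weighted trees fig2_T1 and fig2_T2 simultaneously.]
(o:1,((c:0.8,(b:0.5,(a:0.1)#H1:0.2)s:0.3)v:0.3,#H1:0.4)p:0.2)r;
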