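[Indistinguishable from fig3_N1: the two reticulations above b are stacked in the opposite order, with lengths in the two-parameter family (x=0.5, y=1) that preserves the displayed trees. Canonical form: fig4_Nprime.]
((a:4,((b:6)#H2:1.5)#H1:5.5)t:1,((c:11,#H1:12.5)u1:3,(d:12,#H2:18)u2:10)p:2)r;
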