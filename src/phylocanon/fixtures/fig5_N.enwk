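[Network with three reticulation funnels (out-edge lengths x=y=z=0.05, unidentifiable within (0, 0.1)) displaying 7 distinct weighted trees. Not tree-child, tree-sibling or galled. Canonical form: fig5_Nprime.]
((c:0.5,(b:0.05)#H2:0.6,((#H2:0.45,(e:0.05)#H3:0.35)w:0.05)#H1:0.7)p1:0.3,(d:0.55,#H3:0.65,#H1:0.75)p2:0.4)r;
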