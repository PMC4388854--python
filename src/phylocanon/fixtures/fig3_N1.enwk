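[Network with two nested reticulation funnels above leaf b: the lower reticulation s (in-edges 5 and 9, out-edge 8) feeds the upper reticulation m (other in-edge 6), which leads to b (7). Default length assignment: edge i has length i. Canonical form: fig4_Nprime.]
((a:4,(b:7)#H1:6)t:1,((c:11,(#H1:8)#H2:5)u1:3,(d:12,#H2:9)u2:10)p:2)r;
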