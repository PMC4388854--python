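[Same displayed tree topologies as fig1_N1 but with the two reticulations stacked in the opposite order. Unit lengths; topology-level companion of fig3_N2.]
((a:1,((b:1)#H2:1)#H1:1)t:1,((c:1,#H1:1)u1:1,(d:1,#H2:1)u2:1)p:1)r;
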