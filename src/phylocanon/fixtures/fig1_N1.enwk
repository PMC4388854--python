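[Two-reticulation topology: the lower reticulation feeds the upper one, which leads to leaf b. Unit lengths; topology-level companion of fig3_N1.]
((a:1,(b:1)#H1:1)t:1,((c:1,(#H1:1)#H2:1)u1:1,(d:1,#H2:1)u2:1)p:1)r;
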