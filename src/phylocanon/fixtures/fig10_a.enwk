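[Funnel-free clock-like network (all lengths 1) violating the no-equally-long-paths property: 2 interchangeable cherry units over reticulate leaves a and b. Indistinguishable from, but not isomorphic to, fig10_b/c/d.]
((a#H1:1,b#H2:1)u1:1,(#H1:1,#H2:1)u2:1)r;
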