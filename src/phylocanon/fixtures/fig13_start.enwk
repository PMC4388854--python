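[Reduction worked example: suppressing the funnel reticulation v creates parallel edges that must be merged, which in turn exposes a second funnel. Reduces to fig13_end in four steps (R1, R2, R1, R2).]
(((a:1,b:1)w#H2:1,(#H2:1)#H1:1)u:1,#H1:1,c:1)r;
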