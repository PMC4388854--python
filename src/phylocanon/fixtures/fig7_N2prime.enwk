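[fig2_N2 with the outgroup lineage omitted: the root keeps an outdegree-1 stub of length 0.2. Displays fig7_T1prime and fig7_T2prime.]
((c:0.8,(b:0.5,(a:0.1)#H1:0.2)s:0.3)v:0.3,#H1:0.4)p:0.2;
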