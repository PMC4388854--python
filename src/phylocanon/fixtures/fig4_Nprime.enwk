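[Funnel-free canonical form of fig3_N1 and fig3_N2: leaf b is a reticulation with three in-edges carrying the fully-unzipped path sums 13, 20 and 24.]
((a:4,b#H1:13)t:1,((c:11,#H1:20)u1:3,(d:12,#H1:24)u2:10)p:2)r;
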