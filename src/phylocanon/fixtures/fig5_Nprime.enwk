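[Canonical form of fig5_N; contains a node (w) with indegree 2 and outdegree 2, representing a collapsed reticulate-then-speciation history.]
((c:0.5,b#H1:0.65,(#H1:0.5,e#H2:0.4)w#H3:0.75)p1:0.3,(d:0.55,#H2:0.7,#H3:0.8)p2:0.4)r;
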