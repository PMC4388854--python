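[Displayed tree of fig7_N2prime whose root has outdegree 1 (root edge 0.5, the residual segment of the omitted outgroup lineage).]
(c:0.8,(b:0.5,a:0.3)s:0.3)v:0.5;
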