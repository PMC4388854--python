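[A crack of fig14_N: two root-leaf paths to b sharing only the root prefix and the suffix below the reticulation.]
(((b:1)#H1:1)u:1,(#H1:1)v:1)r;
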