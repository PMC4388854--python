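[A canonical network displaying exactly two trees, with a reticulation leaf; no regular network displays the same set of tree topologies.]
((a:3,h#H1:4)u:1,(#H1:5,b:6)v:2)r;
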