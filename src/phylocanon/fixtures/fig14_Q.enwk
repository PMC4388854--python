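[A wishbone of fig14_N: two root-leaf paths sharing only the one-node prefix at the root.]
((a:1)u:1,(c:1)v:1)r;
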