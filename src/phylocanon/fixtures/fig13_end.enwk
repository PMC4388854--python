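[Canonical form of fig13_start: a single multi-length edge {2,3} records the two alternative evolutionary path lengths.]
((a:1,b:1)w:{2,3},c:1)r;
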