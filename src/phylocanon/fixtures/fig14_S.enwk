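[A crack of fig14_N obtained from a single root-leaf path by attributing two lengths to one of its edges.]
((b:1)m:{1,2}):1;
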