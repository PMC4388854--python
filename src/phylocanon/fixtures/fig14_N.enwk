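[Network illustrating root-leaf paths, wishbones and cracks: see fig14_P (root-leaf path), fig14_Q (wishbone), fig14_R and fig14_S (cracks), all sub-networks of this network.]
((a:1,(b:1)#H1:1)u:1,(#H1:{1,2},c:1)v:1)r;
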