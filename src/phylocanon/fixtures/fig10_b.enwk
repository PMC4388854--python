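[As fig10_a with 3 interchangeable cherry units; adding further copies of the repeated unit extends the family indefinitely.]
((a#H1:1,b#H2:1)u1:1,(#H1:1,#H2:1)u2:1,(#H1:1,#H2:1)u3:1)r;
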