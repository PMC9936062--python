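# Highly restricted Down-syndrome critical region on distal 21q22.13
# (GRCh38 coordinates); duplication of this ~34 kb interval is shared by
# DS subjects.
chr21	37929229	37963130	DS_critical_21q22.13
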