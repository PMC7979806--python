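# S. cerevisiae Mec1 (2368 aa). Pre-filled: the ~400-residue C-terminal
# kinase domain.
name	start	end
kinase	1969	2368
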