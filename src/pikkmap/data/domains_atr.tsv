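# Human ATR (2644 aa). Pre-filled: the ~400-residue C-terminal kinase domain.
name	start	end
kinase	2245	2644
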