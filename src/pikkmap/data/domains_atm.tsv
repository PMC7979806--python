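# Human ATM (3056 aa). Pre-filled: TRD3 (a FAT-domain motif) and the
# ~400-residue C-terminal kinase domain. Edit or extend with your own
# boundaries (name, 1-based inclusive start/end).
name	start	end
TRD3	2195	2475
kinase	2657	3056
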