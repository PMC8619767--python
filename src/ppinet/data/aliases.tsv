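# alias	canonical
# FBG is the fibrinogen protein-level label; FGB is the HGNC gene symbol.
FBG	FGB
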