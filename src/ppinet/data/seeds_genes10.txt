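# Genes associated with post-stroke mortality in the published literature.
SERPINE1
ITGB3
MPG
PROCR
HABP2
COL3A1
FBG
VKORC1
INADL
RETN
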