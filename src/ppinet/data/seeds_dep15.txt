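# Blood proteins significantly altered in ischemic-stroke non-survivors
# versus survivors (differentially expressed proteins, DEPs).
SERPINC1
PROC
PROS1
VWF
F8
FBG
CRP
ALB
TNF
IL10
IL6
TGFB1
FTH1
VCAM1
SELE
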