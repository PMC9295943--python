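name	recognition
ScrFI	CCNGG
NlaIV	GGNNCC
EcoO109I	RGGNCCY
BstUI	CGCG
MscI	TGGCCA
AseI	ATTAAT
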