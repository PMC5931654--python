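# 31 additional commercial restriction endonucleases reported to cut trnL P8
# regions, with recognition motifs per standard REBASE definitions.
# The four core enzymes (AgsI, ApoI, TspDTI, VspI) are defined in code.
name	recognition
AflII	CTTAAG
AccI	GTMKAC
AsuII	TTCGAA
BciVI	GTATCC
BclI	TGATCA
BdaI	TGANNNNNNTCA
BglII	AGATCT
BsaAI	YACGTR
BsaBI	GATNNNNATC
BsmI	GAATGC
CspCI	CAANNNNNGTGG
Eco57I	CTGAAG
Eco57MI	CTGRAG
EcoRI	GAATTC
EcoRV	GATATC
HaeIV	GAYNNNNNRTC
MfeI	CAATTG
MboII	GAAGA
MslI	CAYNNNNRTG
NdeI	CATATG
PsiI	TTATAA
SmlI	CTYRAG
SnaBI	TACGTA
SpeI	ACTAGT
SspI	AATATT
TfiI	GAWTC
TspGWI	ACGGA
TspRI	CASTG
XbaI	TCTAGA
XhoII	RGATCY
XmnI	GAANNNNTTC
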