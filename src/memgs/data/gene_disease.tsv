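gene	disease
APP	AD
PSEN1	AD
PSEN2	AD
SORL1	AD
MAPT	FTD
GRN	FTD
C9orf72	FTD
TARDBP	FTD
CTSF	FTD
VCP	FTD
TBK1	FTD
FUS	FTD
SQSTM1	FTD
CHCHD10	FTD
HTT	OtherDem
CHMP2B	OtherDem
NPC1	OtherDem
PRNP	OtherDem
CSF1R	OtherDem
ITM2B	OtherDem
SNCA	LBD
NOTCH3	VD
HTRA1	VD
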