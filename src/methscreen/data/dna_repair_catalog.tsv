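gene	pathway_group
RAD51	homologous recombination
RAD51B	homologous recombination
RAD51C	homologous recombination;fanconi anemia
RAD51D	homologous recombination
DMC1	homologous recombination
XRCC2	homologous recombination
XRCC3	homologous recombination
RAD52	homologous recombination
RAD54L	homologous recombination
RAD54B	homologous recombination
BRCA1	homologous recombination
BRCA2	homologous recombination;fanconi anemia
SHFM1	homologous recombination
RBBP8	homologous recombination
MRE11A	homologous recombination
RAD50	homologous recombination
NBN	homologous recombination
GEN1	homologous recombination
EME1	homologous recombination
UNG	base excision repair
SMUG1	base excision repair
MBD4	base excision repair
TDG	base excision repair
OGG1	base excision repair
MUTYH	base excision repair
NTHL1	base excision repair
MPG	base excision repair
NEIL1	base excision repair
NEIL2	base excision repair
NEIL3	base excision repair
APEX1	base excision repair
APEX2	base excision repair
LIG3	base excision repair
XRCC1	base excision repair
PNKP	base excision repair
APLF	base excision repair
PARP1	base excision repair
PARP2	base excision repair
PARP3	base excision repair
POLB	base excision repair
MSH2	mismatch excision repair
MSH3	mismatch excision repair
MSH6	mismatch excision repair
MLH1	mismatch excision repair
PMS1	mismatch excision repair
PMS2	mismatch excision repair
MSH4	mismatch excision repair
MSH5	mismatch excision repair
MLH3	mismatch excision repair
EXO1	mismatch excision repair
XPC	nucleotide excision repair
RAD23B	nucleotide excision repair
CETN2	nucleotide excision repair
RAD23A	nucleotide excision repair
XPA	nucleotide excision repair
DDB1	nucleotide excision repair
DDB2	nucleotide excision repair
RPA1	nucleotide excision repair
RPA2	nucleotide excision repair
RPA3	nucleotide excision repair
ERCC3	nucleotide excision repair
ERCC2	nucleotide excision repair
GTF2H1	nucleotide excision repair
GTF2H2	nucleotide excision repair
GTF2H3	nucleotide excision repair
GTF2H4	nucleotide excision repair
GTF2H5	nucleotide excision repair
MNAT1	nucleotide excision repair
CDK7	nucleotide excision repair
CCNH	nucleotide excision repair
ERCC5	nucleotide excision repair
ERCC1	nucleotide excision repair
ERCC4	nucleotide excision repair
LIG1	nucleotide excision repair
ERCC8	nucleotide excision repair
ERCC6	nucleotide excision repair
UVSSA	nucleotide excision repair
XAB2	nucleotide excision repair
MMS19	nucleotide excision repair
FANCA	fanconi anemia
FANCB	fanconi anemia
FANCC	fanconi anemia
FANCD2	fanconi anemia
FANCE	fanconi anemia
FANCF	fanconi anemia
FANCG	fanconi anemia
FANCI	fanconi anemia
BRIP1	fanconi anemia
FANCL	fanconi anemia
FANCM	fanconi anemia
PALB2	fanconi anemia
FAAP20	fanconi anemia
FAAP24	fanconi anemia
FAAP100	fanconi anemia
UBE2T	fanconi anemia
SLX4	fanconi anemia
UBE2A	ubiquitination and modification
UBE2B	ubiquitination and modification
RAD18	ubiquitination and modification
SHPRH	ubiquitination and modification
HLTF	ubiquitination and modification
RNF168	ubiquitination and modification
SPRTN	ubiquitination and modification
RNF8	ubiquitination and modification
RNF4	ubiquitination and modification
UBE2V2	ubiquitination and modification
UBE2N	ubiquitination and modification
USP1	ubiquitination and modification
WDR48	ubiquitination and modification
HERC2	ubiquitination and modification
XRCC6	other
XRCC5	other
PRKDC	other
LIG4	other
XRCC4	other
DCLRE1C	other
NHEJ1	other
POLH	other
POLI	other
POLQ	other
POLK	other
REV3L	other
REV1	other
MAD2L2	other
POLN	other
POLM	other
POLL	other
MGMT	other
ALKBH2	other
ALKBH3	other
NUDT1	other
RRM2B	other
DUT	other
FEN1	other
FAN1	other
TREX1	other
TREX2	other
EXO5	other
APTX	other
SPO11	other
ENDOV	other
DNA2	other
MUS81	other
SLX1A	other
POLG	other
POLD1	other
POLE	other
PCNA	other
H2AFX	other
CHAF1A	other
SETMAR	other
ATRX	other
ATR	other
ATRIP	other
MDC1	other
RAD1	other
RAD9A	other
HUS1	other
RAD17	other
CHEK1	other
CHEK2	other
TP53	other
TP53BP1	other
TOPBP1	other
CLK2	other
PER1	other
RIF1	other
BLM	other
WRN	other
RECQL4	other
RECQL	other
RECQL5	other
ATM	other
MPLKIP	other
DCLRE1A	other
DCLRE1B	other
RPA4	other
NABP2	other
PRPF19	other
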