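gene	direction
B2M	induces
CCL2	induces
CCL20	induces
CCNB1	inhibits
CDK1	inhibits
CDKN1A	induces
CDKN1B	induces
CDKN2A	induces
CDKN2B	induces
CXCL1	induces
CXCL2	induces
CXCL8	induces
EZH2	inhibits
FAS	induces
FOS	induces
GDF15	induces
GLB1	induces
ICAM1	induces
IGF1	induces
IGFBP3	induces
IGFBP5	induces
IGFBP7	induces
IL1A	induces
IL1B	induces
IL6	induces
JUN	induces
LMNB1	inhibits
MKI67	inhibits
MMP1	induces
MMP3	induces
NFKB1	induces
SERPINE1	induces
SERPINE2	induces
STAT1	induces
TGFB1	induces
TIMP1	induces
TIMP2	induces
TNFRSF10C	induces
TP53	induces
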