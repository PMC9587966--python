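gene	category	checkpoint_role
HLA-A	antigen presentation	N/A
HLA-B	antigen presentation	N/A
HLA-C	antigen presentation	N/A
HLA-DPA1	antigen presentation	N/A
HLA-DPB1	antigen presentation	N/A
HLA-DQA1	antigen presentation	N/A
HLA-DQA2	antigen presentation	N/A
HLA-DQB1	antigen presentation	N/A
HLA-DQB2	antigen presentation	N/A
HLA-DRA	antigen presentation	N/A
HLA-DRB1	antigen presentation	N/A
HLA-DRB5	antigen presentation	N/A
ADORA2A	receptor	inhibitory
BTLA	receptor	inhibitory
CTLA4	receptor	inhibitory
EDNRB	receptor	inhibitory
HAVCR2	receptor	inhibitory
IL2RA	receptor	stimulatory
KIR2DL1	receptor	inhibitory
KIR2DL3	receptor	inhibitory
LAG3	receptor	inhibitory
PDCD1	receptor	inhibitory
TIGIT	receptor	inhibitory
TNFRSF14	receptor	stimulatory
TNFRSF18	receptor	stimulatory
TNFRSF4	receptor	stimulatory
TNFRSF9	receptor	stimulatory
CD27	receptor	stimulatory
CD274	ligand	inhibitory
PDCD1LG2	ligand	inhibitory
CD40LG	ligand	stimulatory
CD70	ligand	stimulatory
IFNA1	ligand	stimulatory
IFNA2	ligand	stimulatory
IFNG	ligand	stimulatory
IL10	ligand	inhibitory
IL12A	ligand	stimulatory
IL13	ligand	N/A
IL1A	ligand	N/A
IL1B	ligand	N/A
IL2	ligand	stimulatory
IL4	ligand	N/A
TGFB1	ligand	inhibitory
TNF	ligand	stimulatory
TNFSF4	ligand	stimulatory
TNFSF9	ligand	stimulatory
VEGFA	ligand	inhibitory
VEGFB	ligand	N/A
CD28	co-stimulator	stimulatory
CD40	co-stimulator	stimulatory
CD80	co-stimulator	stimulatory
CD86	co-stimulator	stimulatory
ICOS	co-stimulator	stimulatory
ICOSLG	co-stimulator	stimulatory
BTN3A1	co-inhibitor	stimulatory
BTN3A2	co-inhibitor	stimulatory
CD276	co-inhibitor	inhibitory
VTCN1	co-inhibitor	inhibitory
VSIR	co-inhibitor	inhibitory
SLAMF7	co-inhibitor	stimulatory
ICAM1	cell adhesion	N/A
ITGB2	cell adhesion	N/A
SELP	cell adhesion	N/A
ARG1	other	inhibitory
ENTPD1	other	inhibitory
GZMA	other	N/A
HMGB1	other	N/A
IDO1	other	inhibitory
PRF1	other	N/A
TLR4	other	stimulatory
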