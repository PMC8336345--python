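gene	optic_nerve	optic_nerve_head	retina	trabecular_meshwork
APC	163.958	209.972	-	-
FCHSD2	-	134.694	102.657	-
GJC1	-	-	-	413.055
HRAS	-	-	115.939	-
MSH2	-	-	104.639	-
NIPBL	117.136	165.756	135.751	141.999
PAFAH1B1	1328.740	1130.570	1181.810	1373.830
RAD50	154.762	243.466	135.328	207.515
SOS1	-	139.286	-	135.202
ARHGAP11B	9.146	7.245	8.961	6.504
ATM	-	-	-	10.924
BRCA2	12.279	10.740	13.335	9.430
CCDC73	10.275	5.375	7.035	4.718
FPR2	11.307	13.881	8.970	10.865
HLA-DRB1	2.499	10.861	1.764	-
HLA-DRB5	2.499	10.861	1.764	-
KIF20B	11.902	13.712	-	-
KLRC3	-	8.977	-	5.348
MGAM	-	-	12.893	13.025
PLK4	-	12.940	-	13.407
PRB1	13.405	12.965	6.413	9.600
PRB4	13.405	12.965	6.413	9.600
PSG1	6.338	12.973	-	7.741
PSG3	6.338	9.363	-	7.741
PSG4	6.338	9.363	-	7.741
PSG6	-	12.973	-	-
PSG9	-	12.973	-	-
PTEN	0.127	7.405	3.929	9.512
RHD	5.402	-	11.212	3.473
SCN1A	13.703	10.769	-	8.860
SYCP2	12.574	10.169	7.668	8.315
TBC1D3B	6.780	2.636	8.218	2.528
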