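# Benchmark summary: per-protein experimental conditions, mean/sd of measured R2 (s^-1),
# and prediction RMSE (s^-1). Training-set RMSE is from leave-one-out training; where a
# second value was reported after applying the helix boost it is in rmse_boosted.
name	set	n_res	temperature_K	field_MHz	mean_r2	sd_r2	rmse	rmse_boosted
A1-LCD	train	131	298	800	2.68	0.46	0.60
Ab40	train	40	278	600	3.40	0.92	0.38
Ash1	train	83	278	800	9.80	1.40	1.41
Beclin1	train	165	288	800	5.37	1.03	1.14
CAPRIN1	train	103	303	600	5.34	0.88	0.72
CBP-ID4	train	207	283	700	5.45	2.55	2.01	1.90
GbnD4-DHD	train	91	280	700	6.81	1.55	1.28
ERD14	train	185	288	600	3.96	0.87	0.54
ExsE	train	88	298	600	3.18	0.88	0.76
FCP1	train	85	298	500	2.94	0.54	0.43
FUS	train	163	298	850	3.48	0.51	0.54
GAb1	train	82	298	500	3.99	0.88	0.89
hACTR	train	69	304	600	3.26	0.47	0.49
Hahellin	train	92	298	800	9.94	2.69	2.85
hCSD1	train	141	298	500	3.56	0.93	0.99
HOX-DFD	train	90	298	600	6.98	3.15	1.99
hZIP4-ICL2	train	100	283	800	9.54	2.37	1.58
Jaburetox	train	94	298	800	6.01	2.30	2.27
KRS-NT	train	72	303	600	3.26	0.93	0.83
MBP-xa2	train	70	295	600	3.83	0.60	0.54
MKK4	train	86	278	850	4.49	1.42	0.63
N-Cby	train	63	298		4.19	1.20	1.25
Niv-PNTD	train	406	288	700	5.41	1.82	1.66
NS5A-D2D3	train	268	278	800	8.62	3.85	2.14
NUPR1	train	93	298	600	2.98	0.82	0.76
OPN	train	220	310	800	2.59	0.82	0.54
p53TAD	train	73	298	850	2.72	0.66	0.33
PDEg	train	87	298		3.96	1.05	0.71
PKIa	train	75	300	900	3.41	0.87	0.52
Mev-PNTD	train	304	298	950	2.92	0.59	0.48
ProTa	train	113	283	800	3.40	0.56	0.43
Pup	train	64	298	850	2.66	0.51	0.43
rmBG21	train	199	300	600	4.06	0.90	0.63
RPB1	train	201	277	850	6.48	1.74	1.33
securin	train	202	283	500	5.49	1.13	1.08
Sev-NT	train	124	298	600	3.20	1.42	0.76	0.38
Sic1	train	92	278	500	3.34	0.59	0.48
SKIPN	train	71	298		5.64	1.05	1.46
SLBP-NT	train	113	298	600	3.96	1.40	1.61
a-synuclein	train	140	298	600	2.96	0.53	0.44
SOCS5-JIR	train	70	303	800	4.32	2.36	1.91
tau-K18	train	129	283	700	4.12	0.95	0.83
TC1	train	106	298	600	4.65	1.61	1.24
TDP-43	train	151	283	500	4.07	1.51	0.96
g-tubulin-CT	train	39	288	500	2.23	0.35	0.27
AMOTL1	test	207	283	800	8.45	2.55	2.04
CAHS-8	test	233	303	850	4.43	3.25	2.36	1.92
ChiZ	test	64	298	800	4.33	0.89	0.74
a-endosulfine	test	121	298	800	3.21	0.81	0.48
FtsQ	test	99	305	800	6.44	3.78	2.32	1.71
Pdx1	test	83	298	500	2.98	0.70	0.76
synaptobrevin-2	test	96	278	600	5.54	1.80	0.72
TIA-1	test	91	310	800	4.01	0.89	0.55
YAP	test	122	298	800	3.19	1.44	1.23
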