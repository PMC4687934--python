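gene	log2fc	orientation	conv_mRNA_RT	conv_ncRNA_RT	tandem_RT
NPL3	-6.17	.	.	.	.
YRO2	-4.22	C	1	.	1
THO1	-3.44	C	1	.	.
HXT1	-3.34	T	.	.	1
PTC7	-3.12	C	1	.	.
YJR015W	-2.92	C	.	.	.
CYC1	-2.80	C	1	.	1
YPR172W	-2.79	C	1	.	.
TPO2	-2.70	C	1	.	.
HSP30	-2.51	C	.	.	1
FMP48	-2.42	C	.	.	.
TPO1	-2.36	T	.	1	1
STP4	-2.22	T	.	.	1
UNG1	-2.20	C	1	.	.
PTC2	-2.18	T	.	1	.
ADE17	-2.18	C	1	.	.
ISF1	-2.16	T	.	.	1
HXT4	-2.16	T	.	1	.
FMP12	-2.15	T	.	1	.
EFM3	-2.11	T	.	1	.
FMP41	-2.09	T	.	.	1
GSY1	-2.09	T	.	.	1
SIA1	-2.08	C	1	.	.
TPO4	-2.07	C	.	.	.
SCS7	-2.06	T	.	1	1
MIG3	-2.04	T	.	1	.
WSC4	-2.02	T	.	1	.
PTI1	-1.94	T	.	1	.
HOR2	-1.92	T	.	.	1
IML3	-1.90	C	1	.	1
POA1	-1.89	C	1	.	1
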