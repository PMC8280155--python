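gene_id	NPM1_KD	AURKB_KD	MYC_KD	STL427944	benzamil
BIRC5	-1.44	-1.43	-15.00	-6.05	-0.04
CCNB1	-3.21	-1.64	-7.87	-1.65	-1.30
CCNB2	-2.55	-1.92	-16.66	-2.05	-0.90
CDK1	-3.32	-2.18	-7.66	-2.79	0.29
CDC20	-3.79	-3.26	-24.50	-9.48	-1.12
CDC25A	-1.19	-2.19	-7.96	-6.81	0.16
PLK1	-1.39	-2.30	-10.60	-4.39	0.05
UBE2C	-3.01	-1.27	-12.57	-4.05	-0.19
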