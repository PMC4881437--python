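gene	entrez_id	cna_event	pct_normal_overlap	cox_os_coef	cox_os_p	cox_dfs_coef	cox_dfs_p
ADRA1A	148	Loss	0.42	-0.40185	0.152322	-1.67582	0.001948
ADRA1D	146	Loss	1.15	-0.5968	0.020507	0.066504	0.880385
ADRB3	155	Loss	0	-1.21809	0.002366	-1.12818	0.08601
APOBEC3D	140564	Loss	0	-0.45803	0.24853	-1.56085	0.0224
BRF2	55290	Loss	0	-0.45526	0.02013	0.061887	0.8515
C20orf202	400831	Loss	0.89	-0.80141	0.000481	-0.19907	0.628292
CABIN1	23523	Loss	4.02	-0.47782	0.0210	-0.51601	0.14935
CACNA1I	8911	Loss	0	-0.69524	0.00404	-0.73386	0.082677
CSMD1	64478	Loss	0	-0.01578	0.956357	-1.30789	0.01948
DIO3	1735	Loss	1.76	-0.32561	0.041777	-0.00829	0.973719
EPHX2	2053	Loss	0.42	0.036582	0.61411	-0.30515	0.0099
FAM83F	113828	Loss	0	-0.13746	0.287004	-0.72925	0.00085
GP1BB	2812	Loss	0	-0.56827	0.000246	-0.19289	0.495577
KIAA1656	85371	Loss	0	-0.60241	0.01922	-1.02118	0.032326
LOC339593	339593	Loss	0.17	0.29021	0.385267	-1.12678	0.047789
MCM8	84515	Loss	0	0.043419	0.614947	-0.31948	0.034203
NAT1	9	Loss	0	0.028159	0.713606	-0.36337	0.007197
NAT2	10	Loss	0	-0.09059	0.160865	-0.30169	0.003804
HNF6	3175	Loss	0	-0.66924	0.017955	-0.51152	0.31
PCDHGA11	56105	Loss	0	-0.85799	0.001447	-0.577	0.33928
RAB11FIP1	80223	Loss	0	-0.38036	5.55e-05	-0.02196	0.87
SPAG11A	653423	Loss	68.65	-0.81665	0.001447	-0.13298	0.57
SIRPD	128646	Loss	0.89	-0.89166	0.014166	-0.13392	0.82
TEX43	389320	Loss	0	-0.46611	0.175471	-0.19907	0.01162
TOP1P2	7152	Loss	0	-1.13965	0.005692	0.599602	0.32
WDR5	11091	Loss	0	-0.0007	0.995962	-0.52505	0.024307
ZNF366	167465	Loss	0.07	-0.76274	0.01779	-0.93429	0.09208
ZNF703	80139	Loss	0	-0.32601	0.000744	-0.14954	0.366064
ZNRF3	84133	Loss	0	-0.03445	0.605797	-0.33884	0.002065
ANXA2P2	304	Gain	0	0.478663	0.003259	0.997702	0.000504
CDC42BPA	8476	Gain	0	0.032966	0.690294	0.401718	0.005473
DOK5	55816	Gain	0.57	0.105512	0.1	0.577502	0.002218
DUSP14	11072	Gain	0.70	0.207902	0.047604	0.709569	0.000159
GLIS3	169792	Gain	1.25	0.0916	0.210004	0.397791	0.000566
ING1	3621	Gain	0	0.461934	0.020587	0.127394	0.710857
MPDZ	8777	Gain	0	0.079568	0.406857	0.657405	3.98e-05
PITPNC1	26207	Gain	0	0.257758	0.029048	0.418362	0.026674
SCEL	8796	Gain	0	0.081094	0.202236	0.301113	0.000357
SEMG1	6406	Gain	0	0.098826	0.043099	0.153704	0.061048
SMU1	55234	Gain	0.73	0.36857	0.008896	0.016381	0.942047
USP32	84669	Gain	0	0.162429	0.221638	0.586012	0.01236
VLDLR	7436	Gain	0.14	-0.00629	0.92868	0.323607	0.004972
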