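trait	chrom	pos_bp	pos_cM	lod	pct_variance	a	d
BT	3	20040893	163	5.146	3.130	0.005914	-0.012765
BT	7	1835566	21.5	5.359	3.263	0.010990	0.002648
BT	8	2061023	12.2	7.786	4.783	-0.011989	0.000447
BT	8	19500950	134.2	12.396	7.746	0.016244	-0.003620
FT	3	26882840	190	9.915	4.785	0.012242	-0.001815
FT	5	23418119	111	4.868	2.289	-0.007092	0.003427
FT	7	1835566	21.5	11.241	5.423	0.011243	-0.001854
FT	8	2061023	13	42.112	23.075	-0.021252	0.008320
FT	8	18832553	133	9.374	4.488	0.009159	-0.005437
WS	3	8362080	63	8.774	6.165	-0.056270	-0.366350
WS	6	1052484	10	3.897	2.683	0.172390	-0.055580
WS	7	3192272	31	6.663	4.641	0.205690	-0.053080
WS	8	3118527	17	5.070	3.507	0.178080	-0.028820
PH	1	9004320	49.9	4.166	2.385	-0.012682	0.062053
PH	3	2664384	27	11.394	6.714	0.078301	0.016361
PH	8	1180103	6	20.789	12.728	-0.094477	0.076771
PH	8	10128705	101	6.383	3.686	-0.062798	-0.038649
Lam	8	5481058	36.0	4.334	4.475	-0.075590	0.042250
LLW	3	6744303	61	15.635	14.890	0.089464	-0.031374
LLW	4	38897287	163	4.045	3.620	0.041307	0.028487
LL	1	13071968	72.4	4.458	3.766	0.071867	-0.012244
LL	3	14255522	136.2	5.214	4.423	-0.007829	0.118366
LL	3	29031007	201.4	5.617	4.775	0.066584	-0.094772
LL	7	14342773	68.8	4.284	3.615	-0.020747	0.086727
LL	8	5624776	35	9.433	8.183	-0.104748	0.036218
LW	1	21722429	116	4.313	3.893	0.069770	0.045460
LW	2	19435694	87	3.027	2.713	-0.043950	0.056000
LW	2	25576894	129	5.987	5.452	0.091250	0.012400
LW	8	4356973	32	6.705	6.129	-0.081970	0.036770
NL	3	14075550	130.9	4.581	2.557	0.025147	0.059693
NL	4	7558305	18	4.001	2.228	0.056356	0.010451
NL	5	16624270	70.7	5.384	3.014	-0.055649	0.004690
NL	8	1180103	7	28.109	17.139	-0.119377	0.052082
Pet	1	9074627	51	4.863	15.820	0.064910	0.039080
Pet	7	1835566	21.5	5.689	18.850	0.079160	0.013480
Pti	8	10723493	107.5	3.814	4.749	-0.153200	-0.035130
RD1	1	17879753	95	4.498	2.747	0.068440	-0.020590
RD1	3	623617	2.3	3.632	2.212	0.054350	0.023100
RD1	8	4362085	28	6.942	4.275	-0.074250	0.032990
RD2	1	21954996	115	6.158	3.703	0.079730	0.013670
RD2	7	5769578	42.7	3.839	2.291	-0.056060	0.024000
RD2	8	4356973	31	7.822	4.729	-0.085450	0.033910
RD3	1	9004320	49.9	9.389	5.683	0.102710	-0.005208
RD3	2	23541930	118	4.024	2.392	0.043216	0.071859
RD3	8	2718077	18	7.209	4.332	-0.087105	0.022622
RD4	1	21722429	115.3	4.330	2.678	0.061815	0.014845
RD4	8	4356973	32	7.814	4.888	-0.078677	0.035138
Ssh	4	36501835	137.7	3.859	2.842	-0.119930	-0.038550
Ssh	5	5129643	35.5	4.875	3.605	0.126580	0.031450
SH	1	29847516	162	3.594	1.778	-0.029247	0.036282
SH	3	4035375	36	13.598	6.984	0.074366	0.005981
SH	4	38897287	160	4.386	2.177	0.042699	-0.004189
SH	8	1180103	6	26.851	14.500	-0.091994	0.070533
SH	8	10506892	102	7.858	3.951	-0.059677	-0.004408
SLD	3	3491752	29	5.760	4.162	-0.052426	-0.018081
SLL	6	21070306	134.8	5.918	9.356	0.046349	0.011155
SLL	8	3118527	15	3.967	6.163	-0.035380	0.011240
SLW	8	18832576	132.5	13.228	20.958	-0.084603	0.017725
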