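trait	abbrev	mean_nemorensis	mean_sagittata	p_reported
Days to Bolting	BT	157.2857	169.2857	7.67733569186116e-29
Days to Flowering	FT	183.5714	193.4286	9.92819572840268e-26
Fertility Score	WS	0.0298	0.0295	0.735982604
Inflorescence Height	PH	35.2500	34.5714	0.121159231
Lamina Length	Lam	1.2729	1.4646	0.011923973
Lamina L:W	LLW	1.4760	1.7938	3.3370726452435e-10
Leaf Length	LL	1.5562	1.7161	0.787509948
Leaf Width	LW	0.8589	0.8213	0.103685956
No. of Stem Leaves	NL	28.1429	18.1429	2.24983890109023e-33
Petal Length	Pet	4.0569	5.3579	6.04691680241348e-34
Petiole Length	Pti	0.2833	0.2516	0.002181075
Rosette Diameter 1	RD1	1.8331	2.2419	0.713598816
Rosette Diameter 2	RD2	3.2946	3.6893	0.081329783
Rosette Diameter 3	RD3	3.3611	3.4424	0.072384866
Rosette Diameter 4	RD4	3.8805	3.9110	0.111109462
Side Shoots	Ssh	2.7857	2.1429	0.205905044
Stem Height	SH	40.4286	34.4286	3.02830254946091e-07
Stem Leaf Density	SLD	0.6979	0.5271	3.18884502716871e-20
Stem Leaf Length	SLL	2.3894	2.7921	0.004243421
Stem Leaf Width	SLW	1.4021	1.2337	0.014377018
Petiole L:Lamina L	PL	0.2464	0.1886	0.001013407
Ground Shoots	Gsh	0.2143	1.2857	3.27306200327204e-05
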