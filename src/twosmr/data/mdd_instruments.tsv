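snp	chrom	pos	effect_allele	other_allele	eaf	beta	se	pval	r2_printed	f_printed
rs301799	1	8489302	T	C	0.5694	-0.0250	0.0035	1.36e-12	1.08e-3	247.571
rs1002656	1	37192741	T	C	0.7033	-0.0266	0.0038	3.74e-12	1.04e-3	238.531
rs1466887	1	37709328	T	C	0.5511	-0.0199	0.0036	4.12e-8	6.91e-4	158.258
rs11579246	1	50559162	A	G	0.9067	0.0381	0.0061	5.71e-10	8.66e-4	198.380
rs1890946	1	52342427	T	C	0.4671	-0.0235	0.0035	2.68e-11	9.69e-4	222.078
rs10789214	1	67146817	T	C	0.5661	0.0193	0.0035	4.44e-8	6.45e-4	147.799
rs2568958	1	72765116	A	G	0.6156	0.0373	0.0036	8.47e-25	2.32e-3	532.085
rs10890020	1	73668836	A	G	0.5156	-0.0277	0.0035	4.03e-12	1.35e-3	309.627
rs113188507	1	80809636	A	G	0.2838	0.0221	0.0039	1.87e-8	7.00e-4	160.366
rs10913112	1	175913828	T	C	0.3767	-0.0264	0.0036	3.40e-13	1.15e-3	264.386
rs72710803	1	177428018	A	C	0.9121	-0.0410	0.0062	5.29e-11	9.50e-4	217.726
rs169235	1	181740924	A	G	0.753	-0.0229	0.0041	2.98e-8	6.88e-4	157.559
rs17641524	1	197704717	T	C	0.2091	-0.0320	0.0043	1.52e-13	1.19e-3	273.601
rs12052908	2	22503044	A	T	0.5325	-0.0220	0.0035	4.44e-10	8.49e-4	194.646
rs1568452	2	58012833	T	C	0.3851	0.0248	0.0036	8.12e-12	1.03e-3	235.290
rs7585722	2	86819128	T	C	0.8458	-0.0269	0.0048	2.68e-8	6.65e-4	152.452
rs1226412	2	157111313	T	C	0.7917	0.0256	0.0043	3.46e-9	7.62e-4	174.590
rs62188629	2	208044470	A	G	0.3136	0.0236	0.0038	7.13e-10	8.45e-4	193.676
rs4346585	3	44736493	T	C	0.696	-0.0236	0.0038	7.13e-10	8.31e-4	190.373
rs13084037	3	49214066	A	G	0.774	-0.0245	0.0042	7.08e-9	7.40e-4	169.616
rs7624336	3	53244151	T	G	0.2087	0.0238	0.0043	3.96e-8	6.60e-4	151.110
rs141954845	3	61192911	A	G	0.388	0.0229	0.0037	8.15e-10	8.78e-4	201.167
rs6783233	3	117509984	T	C	0.2833	0.0218	0.0039	2.90e-8	6.80e-4	155.875
rs1095626	3	157977962	T	C	0.5799	-0.0264	0.0035	7.13e-14	1.20e-3	274.319
rs7685686	4	3207142	A	G	0.5753	0.0202	0.0036	2.57e-8	7.03e-4	161.050
rs34937911	4	42110353	T	C	0.8838	0.0304	0.0055	4.13e-8	6.69e-4	153.315
rs45510091	4	123186393	A	G	0.9472	0.0448	0.0080	1.83e-8	7.08e-4	162.149
rs35553410	4	131237381	T	C	0.7462	-0.0244	0.0040	1.42e-9	7.95e-4	182.146
rs7659414	4	177350956	A	C	0.5782	-0.0201	0.0035	1.20e-8	6.95e-4	159.169
rs60157091	5	61509655	T	C	0.515	0.0200	0.0035	1.42e-8	7.04e-4	161.395
rs3099439	5	87545318	T	C	0.5288	-0.0276	0.0035	5.05e-15	1.34e-3	306.673
rs10061069	5	93071630	C	G	0.2212	-0.0275	0.0042	8.15e-11	9.18e-4	210.467
rs30266	5	103972357	A	G	0.3296	0.0308	0.0037	1.45e-16	1.48e-3	338.688
rs11135349	5	164523472	A	C	0.4713	-0.0295	0.0035	6.04e-17	1.53e-3	350.376
rs200949	6	27835435	A	G	0.8744	0.0480	0.0053	2.53e-19	1.78e-3	408.881
rs9363467	6	66565703	T	C	0.6035	0.0237	0.0036	6.44e-11	9.48e-4	217.135
rs7758630	6	101387304	A	T	0.4051	-0.0225	0.0036	5.56e-10	8.60e-4	197.094
rs1933802	6	105365891	C	G	0.4536	-0.0223	0.0035	2.57e-10	8.69e-4	199.111
rs2876520	6	142996618	C	G	0.5271	-0.0230	0.0036	2.29e-10	9.30e-4	213.024
rs725616	6	147950422	T	C	0.3644	0.0204	0.0036	1.87e-8	6.80e-4	155.705
rs2029865	6	165121844	A	T	0.4534	-0.0201	0.0035	1.20e-8	7.06e-4	161.743
rs3823624	7	2110346	T	C	0.8067	0.0272	0.0045	1.99e-9	8.13e-4	186.370
rs2043539	7	12253880	A	G	0.4177	0.0273	0.0035	9.89e-15	1.28e-3	292.880
rs2247523	7	82454404	C	G	0.5319	-0.0207	0.0035	4.38e-9	7.52e-4	172.344
rs16887442	7	82936909	T	C	0.4347	0.0203	0.0035	8.62e-9	7.14e-4	163.585
rs58104186	7	109099919	A	G	0.4689	0.0237	0.0035	1.82e-11	9.86e-4	225.980
rs7807677	7	117502574	T	C	0.5505	0.0237	0.0035	1.82e-11	9.80e-4	224.543
rs7837935	8	65562019	T	G	0.1522	-0.0292	0.0049	3.34e-9	7.76e-4	177.732
rs67436663	8	71347626	C	G	0.2402	-0.0259	0.0042	9.37e-10	8.63e-4	197.776
rs1354115	9	2983774	A	C	0.6243	0.0210	0.0036	7.08e-9	7.29e-4	167.093
rs1982277	9	11513019	T	C	0.7594	0.0279	0.0041	1.45e-11	1.00e-3	229.770
rs263645	9	17016503	A	T	0.5438	0.0221	0.0035	3.70e-10	8.54e-4	195.740
rs3793577	9	23737627	A	G	0.4665	-0.0229	0.0035	8.41e-11	9.20e-4	210.846
rs59283172	9	25232978	A	G	0.1069	-0.0329	0.0057	1.02e-8	7.29e-4	166.938
rs34653192	9	31124452	C	G	0.3196	-0.0229	0.0038	2.23e-9	8.04e-4	184.220
rs7030813	9	36999369	T	C	0.3736	0.0253	0.0036	3.07e-12	1.06e-3	242.005
rs10817969	9	119731045	T	G	0.7173	0.0261	0.0039	3.11e-11	9.74e-4	223.163
rs913930	9	120484009	A	G	0.6433	-0.0208	0.0037	2.42e-8	7.00e-4	160.371
rs2670139	9	126634255	T	C	0.7609	-0.0266	0.0041	1.21e-10	9.07e-4	207.959
rs997934	10	1795194	T	C	0.3795	0.0198	0.0036	4.81e-8	6.51e-4	149.128
rs1021363	10	106610839	A	G	0.3547	0.0303	0.0037	4.41e-16	1.48e-3	339.536
rs1448938	11	30892824	A	G	0.4171	0.0214	0.0035	1.30e-9	7.85e-4	179.868
rs2509805	11	57650796	T	C	0.3209	0.0220	0.0038	9.17e-9	7.44e-4	170.387
rs198457	11	61471678	T	C	0.1925	-0.0292	0.0046	2.99e-10	9.34e-4	214.116
rs58621819	11	65314830	A	T	0.7903	-0.0245	0.0043	1.57e-8	7.01e-4	160.696
rs7117514	11	70544937	A	G	0.5417	-0.0204	0.0035	7.29e-9	7.28e-4	166.899
rs7932640	11	88744425	T	C	0.4417	0.0281	0.0035	1.62e-15	1.37e-3	314.610
rs61902811	11	113370758	A	G	0.3682	-0.0257	0.0036	1.40e-12	1.08e-3	248.232
rs2187490	11	118713180	T	G	0.9106	-0.0338	0.0061	3.82e-8	6.56e-4	150.236
rs57344483	11	127022560	A	G	0.9259	-0.0380	0.0068	1.82e-8	6.99e-4	160.041
rs78337797	12	23987925	T	G	0.8781	0.0306	0.0055	3.37e-8	7.07e-4	161.910
rs56314503	12	84465022	T	G	0.7487	-0.0254	0.0040	2.95e-10	8.56e-4	196.096
rs10774600	12	110741356	T	C	0.1656	-0.0267	0.0048	3.39e-8	6.95e-4	159.125
rs3213572	12	121205078	A	G	0.4745	0.0217	0.0035	7.61e-10	8.28e-4	189.682
rs1409379	13	31907741	T	C	0.7641	0.0249	0.0041	1.67e-9	7.88e-4	180.538
rs1343605	13	53647048	A	C	0.384	0.0313	0.0036	6.23e-18	1.63e-3	374.453
rs9592461	13	66941792	A	G	0.4874	0.0216	0.0035	9.10e-10	8.22e-4	188.308
rs9545360	13	80826373	A	C	0.1807	-0.0271	0.0046	5.02e-9	7.67e-4	175.642
rs4772087	13	99115041	T	C	0.3732	0.0227	0.0036	3.91e-10	8.50e-4	194.725
rs61990288	14	42074726	A	G	0.5083	-0.0260	0.0035	1.68e-13	1.19e-3	272.966
rs1956373	14	60141822	T	G	0.7436	-0.0226	0.0040	2.06e-8	6.87e-4	157.309
rs1152578	14	64697037	T	C	0.4357	-0.0218	0.0035	6.36e-10	8.24e-4	188.759
rs1045430	14	75130235	T	G	0.4792	-0.0253	0.0035	7.31e-13	1.13e-3	258.085
rs10149470	14	104017953	A	G	0.4869	-0.0267	0.0035	3.72e-14	1.26e-3	287.749
rs8037355	15	37643831	T	C	0.5556	-0.0233	0.0035	3.94e-11	9.45e-4	216.551
rs34488670	15	47684936	T	C	0.7887	-0.0252	0.0043	6.03e-9	7.46e-4	170.962
rs7193263	16	6315880	A	G	0.6679	-0.0239	0.0038	4.33e-10	8.93e-4	204.683
rs7198928	16	7666402	T	C	0.6159	0.0239	0.0036	4.45e-11	9.53e-4	218.305
rs7200826	16	13066833	T	C	0.2551	0.0280	0.0040	3.74e-12	1.05e-3	240.685
rs56887639	16	13755530	A	G	0.7264	-0.0278	0.0039	1.51e-12	1.08e-3	248.148
rs12923444	16	21639710	A	C	0.5625	-0.0214	0.0035	1.30e-9	7.95e-4	182.063
rs75581564	17	27363750	A	G	0.1165	0.0301	0.0054	3.17e-8	6.58e-4	150.640
rs12967855	18	35138245	A	G	0.3295	0.0265	0.0037	1.18e-12	1.09e-3	250.655
rs7227069	18	50731802	A	G	0.4326	0.0238	0.0035	1.50e-11	9.80e-4	224.619
rs62091461	18	52488672	T	C	0.2274	-0.0254	0.0042	1.95e-9	7.99e-4	183.108
rs12966052	18	52751639	C	G	0.1805	-0.0314	0.0046	1.25e-11	1.03e-3	235.617
rs12967143	18	53099012	C	G	0.6984	-0.0312	0.0038	3.70e-16	1.44e-3	331.297
rs7241572	18	77580712	A	G	0.201	0.0280	0.0044	2.70e-10	8.88e-4	203.406
rs33431	19	30939989	T	C	0.6144	0.0198	0.0036	4.81e-8	6.55e-4	150.036
rs143186028	20	39997404	T	G	0.1778	0.0277	0.0046	2.29e-9	7.91e-4	181.201
rs12624433	20	44680853	A	G	0.2584	0.0233	0.0040	7.44e-9	7.34e-4	168.058
rs5995992	22	41487218	T	C	0.7155	-0.0266	0.0039	1.30e-11	1.02e-3	232.689
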