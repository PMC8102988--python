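sample_id	salinity	temperature	ph	no3	no2	nh4	po4	silicate	chlorophyll_a	doc	depth	channel_km
S01	0	21.49069642	8.015645634	117.3447894	1.588904784	5.886594082	2.37707741	60.85387315	154.7891693	6.362575836	2.578385093	0
S02	0.1599235984	22.21253334	7.965975609	117.5551544	1.32959435	5.785939243	2.721732747	60.96581694	150.311797	7.342485671	2.064310664	9.469565217
S03	0.3836461543	21.6986623	7.959843764	114.8812819	1.555991735	6.078333003	2.701261194	58.43542548	148.7676803	6.897203007	2.197539556	18.93913043
S04	0.6950857409	21.78377882	8.045992772	118.9441414	1.29237129	5.489839992	2.3728082	60.61033968	147.2050801	7.428281275	2.59096643	28.40869565
S05	1.125682895	22.28775257	7.961736565	117.8499516	1.385134736	5.900288446	2.584485103	58.28548547	141.3006449	7.02464583	2.572922791	37.87826087
S06	1.715438483	21.75930823	8.009695537	119.8915675	1.446581762	5.746483808	2.255694507	53.52902289	133.5983289	7.118272207	2.63481879	47.34782609
S07	2.512830971	21.5852	7.98921852	119.1739407	1.608691521	6.177900251	2.168950682	58.23214883	141.2150966	6.597813648	2.485868556	56.8173913
S08	3.572368985	21.62347309	8.054367356	107.4745969	1.519574009	5.652346621	2.118990246	52.15197483	136.4010668	6.247609182	2.564877318	66.28695652
S09	4.94815142	21.33334538	8.06176627	110.04607	1.185074729	4.845892089	2.094939995	61.93352071	117.9618394	6.588509927	3.588076936	75.75652174
S10	6.682066767	20.95002513	7.956426108	93.73343596	1.225458104	4.588720943	2.005349939	51.11266912	112.2365854	6.638104686	3.856806166	85.22608696
S11	8.78701304	20.94114913	8.120099993	96.00279461	1.154616559	4.44039055	2.056347061	46.34956161	91.00420082	6.365880296	5.194536746	94.69565217
S12	11.22924218	21.19211448	8.078200676	79.96576288	0.9195384761	3.680580798	2.213766583	46.19678969	82.74778345	6.143547872	5.928028085	104.1652174
S13	13.91826084	20.4799846	8.23508306	74.24896327	0.7463833537	3.282406316	1.786383163	44.13485735	60.76040646	5.716071875	6.674800113	113.6347826
S14	16.71357357	19.97478158	8.205956373	71.28810343	1.14369347	4.561537627	1.562514638	40.23007946	55.51405556	5.5935214	8.301393892	123.1043478
S15	19.4509719	19.56738244	8.236067787	56.25582396	1.03800733	3.043755225	1.657740107	32.63237098	39.26637218	4.864844123	9.714528912	132.573913
S16	21.97932893	19.40329428	8.095075518	54.41546419	0.8081972408	3.526930998	1.397015665	31.2629926	23.38823962	4.824812299	10.67552776	142.0434783
S17	24.19150795	19.06574154	8.321797007	38.07168459	0.5956450103	2.436495298	1.340390837	26.95715446	22.57671604	4.186168634	11.34091798	151.5130435
S18	26.03718588	18.38334243	8.255326922	35.98873594	0.5088484488	2.317416049	1.296390537	22.44057694	21.15429578	4.458769377	12.64933887	160.9826087
S19	27.51697142	18.60154044	8.201276634	37.4606528	0.5104961512	1.608706344	1.230818166	15.49026742	10.61363527	4.238571855	13.41036586	170.4521739
S20	28.66597859	18.31683543	8.294024375	38.60748021	0.7955556865	2.613231151	1.007732004	18.4257425	7.876198991	4.236562595	14.16420221	179.9217391
S21	29.53614162	18.70364196	8.350768392	22.97356561	0.5676632702	1.848494984	1.031113595	9.392492649	6.5232053	4.449605896	14.55568577	189.3913043
S22	30.18274773	18.0421291	8.214975414	34.26120721	0.7977675747	2.566307716	1.175779454	13.49956213	6.083644263	4.092727092	14.22652649	198.8608696
S23	30.65648989	18.41985242	8.35013327	26.40485262	0.3876065598	1.575863108	0.9575403804	19.55276767	10.11532866	3.155387371	14.62822043	208.3304348
S24	31	17.65329455	8.28529061	35.0568973	0.7087465761	2.306914502	0.9610305579	15.50719082	10.1050414	4.406428371	15.24228525	217.8
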