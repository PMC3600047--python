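pair_id	clade_rich	clade_poor	genes_available	richness_rich	richness_poor	total_rich	total_poor	dN_rich	dN_poor	dS_rich	dS_poor	omega_rich	omega_poor
1	Persoonia	Garnieria + Acidonia	2	100	2	0.00303	0.00097	0.00331	0.00105	0.00299	0.00170	1.10704	0.61562
2	Symphionema	Agastachys	4	2	1	0.01329	0.00828	0.00990	0.00403	0.01713	0.02123	0.57818	0.18971
3	Cenarrhenes + Dilobeia	Beaupreopsis	1	3	1	0.01703	0.00936	0.00379	0.00315	0.02849	0.01317	0.13315	0.23892
4	Conospermum + Synaphea	Stirlingia	4	104	7	0.03480	0.02865	0.01312	0.01164	0.06744	0.05841	0.19454	0.19922
5	Protea	Faurea	5	112	15	0.00872	0.00660	0.00588	0.00589	0.01364	0.01052	0.43081	0.55959
6	Petrophile	Aulax	3	53	3	0.01424	0.01537	0.00723	0.01279	0.02834	0.02951	0.25512	0.43337
7	Paranomus	Vexatorella	2	19	4	0.00130	0.00130	0.00187	0.00047	1.00E-09	0.00445	1.87E+06	0.10504
8	Leucospermum	Orothamnus + Diastella + Mimetes	2	48	21	0.00129	0.00183	0.00095	0.00187	0.00292	0.00296	0.32577	0.63319
9	Alloxylon + Oreocallis	Embothrium	4	6	1	0.00641	0.00577	0.00418	0.00323	0.00931	0.00625	0.44871	0.51730
10	Stenocarpus + Strangea	Lomatia	6	26	12	0.01094	0.00625	0.00602	0.00395	0.01962	0.01304	0.30693	0.30245
11	Grevillea + Finschia + Hakea	Buckinghamia	6	515	2	0.01847	0.00306	0.01027	0.00118	0.03031	0.00916	0.33881	0.12925
12	Virotia	Athertonia	1	6	1	0.00091	0.00754	0.00097	0.00535	1.00E-09	0.01243	9.71E+05	0.43028
13	Panopsis + Brabejum	Macadamia	4	27	9	0.00966	0.00752	0.00577	0.00623	0.01995	0.01371	0.28920	0.45473
14	Hicksbeachia	Gevuina	1	2	1	0.00229	0.00220	0.00261	0.00098	0.00095	0.00309	2.75046	0.31894
15	Euplassa	Sleumerodendron + Kermadecia + Turrillia	3	20	8	0.00318	0.00262	0.00281	0.00199	0.00448	0.00619	0.62802	0.32064
16	Banksia + Dryandra	Austromuellera + Musgravea	6	169	4	0.01403	0.01107	0.00893	0.00525	0.02906	0.02498	0.30745	0.21017
17	Roupala + Neorites	Orites	6	34	8	0.00620	0.00420	0.00286	0.00229	0.01367	0.00483	0.20891	0.47439
18	Darlingia	Floydia	2	2	1	0.00219	0.00297	0.00236	0.00132	0.00295	0.00571	0.79752	0.23042
19	Lambertia	Xylomelum	4	10	6	0.02536	0.02419	0.01116	0.01036	0.05726	0.04448	0.19491	0.23296
20	Helicia	Hollandaea	3	97	4	0.00149	0.00039	0.00094	0.00000	0.00304	0	3.10E-01	0
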