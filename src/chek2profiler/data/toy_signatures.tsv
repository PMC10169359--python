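channel	TS1	TS2	TS3	TS4	TS5	TS6
A[C>A]A	0.0692320028	0.0025435499	9.8e-05	0.00112538	0.0002582	0.00286845
A[C>A]C	0.0423544917	0.00046928	0.00132697	0.00053794	0.00038512	0.00018092
A[C>A]G	0.1047761342	0.00067017	0.00036017	9.13e-05	0.00132241	0.00206024
A[C>A]T	0.1016121341	0.00125175	0.0009034	0.00124095	0.00095069	0.00105313
C[C>A]A	0.0723554829	0.00190573	8.486e-05	0.0017662499	0.00034407	0.00029882
C[C>A]C	0.1073366443	0.00022717	0.00060603	0.00021961	0.00123088	9.755e-05
C[C>A]G	0.1180097147	0.00084565	0.0010527	8.162e-05	0.00054312	9.306e-05
C[C>A]T	0.0391557016	0.00018442	0.00015982	0.00053576	0.00091963	0.00010178
G[C>A]A	0.0564575423	0.00014171	0.00019787	0.00015991	0.0003132	0.00207825
G[C>A]C	0.0613121625	0.00109067	4.316e-05	0.000856	0.00059355	0.00094098
G[C>A]G	0.0139341006	0.00101991	0.00051678	0.00013082	0.00015095	5.22e-06
G[C>A]T	0.0320877413	0.00119075	0.00349791	6.781e-05	0.00068058	0.0005251
T[C>A]A	0.0070078103	0.00056383	0.00111735	0.00038337	0.00155392	0.00070691
T[C>A]C	0.0192393508	0.00024575	0.00059813	0.00051613	5.94e-05	0.00060878
T[C>A]G	0.0481229819	6.795e-05	0.00029749	0.00025697	0.00046039	0.00192171
T[C>A]T	0.0425700117	0.0004009	0.00073136	0.00092261	0.00078756	0.0015252
A[C>G]A	0.0007819	0.1381520472	0.0001235	5.236e-05	0.00015117	0.00013198
A[C>G]C	0.0014733201	0.0270054495	0.00047663	0.00057969	0.00035636	0.0009751
A[C>G]G	0.00068828	0.1269185575	0.00230318	0.00033639	0.00033405	0.00157702
A[C>G]T	0.00080919	0.0617526988	3.23e-05	4.228e-05	0.00021096	0.00180705
C[C>G]A	9.067e-05	0.0973043281	0.00092886	0.00021517	8.15e-06	7.595e-05
C[C>G]C	0.00085179	0.0593607188	4.341e-05	0.00069507	0.00108833	0.00121752
C[C>G]G	0.00032376	0.048391109	0.00020091	0.0013577799	0.00136118	6e-06
C[C>G]T	0.00062134	0.0195064996	0.00132495	0.00078438	7.727e-05	4.579e-05
G[C>G]A	0.00045879	0.1592506568	0.00046113	2.629e-05	0.00062094	0.00071517
G[C>G]C	0.00118394	0.0257546095	0.00012678	0.00035465	0.0002033	0.00141395
G[C>G]G	0.00088143	0.0093414998	0.00183628	0.00048155	0.00061782	0.00055482
G[C>G]T	0.00026673	0.0297201894	4.316e-05	0.0035485699	0.00085037	1.119e-05
T[C>G]A	0.0033540801	0.0132088597	3.104e-05	0.00016511	0.00060996	0.00017491
T[C>G]C	0.00033718	0.0892258882	0.00010105	7.146e-05	0.00064616	0.00079209
T[C>G]G	0.0013647901	0.0065693399	0.00010686	0.00024892	0.00222999	0.00081843
T[C>G]T	0.00095885	0.0213457796	0.00118934	8.546e-05	0.00225231	0.00064891
A[C>T]A	0.00033252	0.00051197	0.0698061893	7.344e-05	2.926e-05	0.00069567
A[C>T]C	0.0014914001	0.00029744	0.0941048591	0.00068296	3.616e-05	0.00041013
A[C>T]G	5.487e-05	0.00209214	0.0685642093	0.00090648	0.00050856	0.00101469
A[C>T]T	0.0014463501	0.00037614	0.0529365495	0.00081675	0.00052589	0.00103392
C[C>T]A	0.00121353	0.00153263	0.0830544592	0.00039134	0.00280231	0.00029575
C[C>T]C	0.00056646	0.00031559	0.0538314195	0.0001974	0.00028296	0.00022416
C[C>T]G	0.00039708	0.00015919	0.0630005894	7.134e-05	0.00018689	0.00014505
C[C>T]T	0.00016358	0.0024861	0.0838853192	0.0021718199	0.00324413	0.00148702
G[C>T]A	0.00074968	0.00076746	0.0196481998	0.00080073	0.00092566	0.00017563
G[C>T]C	0.0024548801	1.17e-05	0.0170654698	0.0020929999	0.00051584	0.00109399
G[C>T]G	0.0044564502	0.00161595	0.0309883597	0.0014692299	0.00064441	0.00025839
G[C>T]T	0.00018985	0.00055214	0.1351736386	0.0019700299	0.00046041	0.00068725
T[C>T]A	0.00022616	0.00224257	0.0346454497	0.00031988	0.0002278	0.00078189
T[C>T]C	0.00046134	0.00069822	0.0692288893	0.0026622499	0.00059807	0.00102879
T[C>T]G	6.355e-05	0.00010514	0.0367901596	0.00054263	0.00106175	0.00134792
T[C>T]T	0.00068437	0.0027132099	0.0207829198	0.00109926	0.00134209	0.00202301
A[T>A]A	0.00024187	0.00045706	0.00121417	0.0122920295	0.00183027	0.00033405
A[T>A]C	0.00103613	0.00137289	0.00284366	0.0787821168	0.00125372	0.00012988
A[T>A]G	9.859e-05	0.00028189	0.00159967	0.0513110579	7.224e-05	0.00190134
A[T>A]T	3.67e-06	0.0019282	0.00055871	0.0091901696	0.00060776	0.00251503
C[T>A]A	7.185e-05	0.00113818	0.00023036	0.049081808	0.00027701	0.00197254
C[T>A]C	0.00014574	0.00048933	0.00112637	0.0766132169	0.00026944	0.00088277
C[T>A]G	0.0026179401	0.00193262	0.00157359	0.0526926779	0.00057479	0.00172053
C[T>A]T	0.0023370401	0.00012315	0.00011093	0.1169996153	0.00011407	5.18e-06
G[T>A]A	0.00058436	0.0010019	0.00012842	0.0443738382	0.00015827	0.00050239
G[T>A]C	0.00055857	0.00036041	0.0017406	0.0196740492	5.362e-05	0.00248446
G[T>A]G	0.00090692	0.00024938	0.0001918	0.0273792889	0.00094189	0.0004208
G[T>A]T	0.00058152	0.00139934	0.00093905	0.0597040176	0.00120916	0.00144857
T[T>A]A	0.0017693001	0.00127141	0.00112363	0.0793535368	0.00010779	0.00054971
T[T>A]C	0.0017491701	7.11e-05	0.00060796	0.0163099593	0.00045622	0.00240553
T[T>A]G	0.0012592401	0.00188192	0.00274152	0.0663909373	0.00079752	4.586e-05
T[T>A]T	0.00084918	0.00053382	0.000831	0.1703892532	0.00115864	0.00073287
A[T>C]A	0.00034983	0.00022882	0.00143401	0.00098345	0.1095461711	0.00087807
A[T>C]C	0.0015076201	0.00034848	5.416e-05	0.0018911799	0.00282018	0.00201267
A[T>C]G	5.965e-05	0.0001299	1.32e-05	0.0005772	0.0443407704	0.00257799
A[T>C]T	0.00016144	0.00175246	0.00073265	0.00060312	0.0144188801	0.00075997
C[T>C]A	0.0025044601	0.00244431	0.00104945	0.00028632	0.0342455103	0.00016231
C[T>C]C	6.25e-06	9.776e-05	0.00093069	0.00064066	0.0593019506	0.00116755
C[T>C]G	0.00024846	0.00049169	0.00087273	0.00062975	0.0781996508	0.00113022
C[T>C]T	0.0002647	0.00027429	0.00254774	0.0024696999	0.0058813801	0.00164381
G[T>C]A	0.00048901	0.00199362	0.00044442	0.0013317299	0.0831656408	0.00132394
G[T>C]C	0.00062877	0.00012913	0.00043341	0.00092924	0.0653131907	0.00025193
G[T>C]G	0.00056078	0.00045844	0.00115091	0.00071021	0.0192596302	0.00014273
G[T>C]T	0.00035648	0.0003474	0.00050483	0.00024922	0.1197893612	0.00040656
T[T>C]A	0.00057	0.00100482	6.822e-05	0.00116224	0.0367828704	0.00044635
T[T>C]C	0.00014209	0.00034544	3.133e-05	0.0014742499	0.0186396202	0.00073711
T[T>C]G	0.00013857	0.00041898	0.00020987	0.00038462	0.1291678113	0.0002932
T[T>C]T	0.0006928	0.00046178	0.00026613	0.0027638799	0.1175152512	2.588e-05
A[T>G]A	0.00044481	0.00092161	0.00107131	0.0014596099	0.00079926	0.0243712602
A[T>G]C	0.00017854	0.0028522699	0.00189716	0.0010827	0.0005006	0.1326735213
A[T>G]G	0.00018588	0.00043979	0.00119338	2.937e-05	0.00038322	0.0650364107
A[T>G]T	0.00060891	6.147e-05	0.00048136	0.00120787	0.0006232	0.0650834307
C[T>G]A	0.00071069	0.0022957	0.00313328	0.00086629	0.00024613	0.0111313201
C[T>G]C	0.00030126	0.00020127	0.00090381	0.0016732399	0.00061607	0.0517657205
C[T>G]G	0.0010642	0.00067748	0.00190454	0.00033823	0.00168327	0.0523147905
C[T>G]T	0.00039211	4.705e-05	0.00164686	0.00055131	0.00062743	0.101821771
G[T>G]A	3.385e-05	0.00064874	0.0007052	0.0027884999	8.829e-05	0.0655945707
G[T>G]C	0.00089094	2.586e-05	7.862e-05	0.0001219	0.00033515	0.0751758808
G[T>G]G	0.00023941	0.00061706	0.00181426	0.0020179999	0.00036913	0.0731609507
G[T>G]T	0.0029236501	0.00010527	0.00064359	0.00068087	0.0032929	0.0081375001
T[T>G]A	0.00105139	0.00074382	0.00054676	0.0019614899	5.341e-05	0.0313594203
T[T>G]C	0.0016556301	0.00117059	0.00040453	0.00056092	0.00013925	0.0257552803
T[T>G]G	0.00034486	0.00117077	2.992e-05	0.0013116099	0.00115262	0.0511367705
T[T>G]T	0.0005197505999998276	0.000496318899999909	0.0008121692000001558	0.0015176495000001889	0.005255610600000041	0.09473436159999994
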