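# Tabulated backbone bending potential.
# columns: angle (rad), energy (kJ/mol). Smooth default peaked at
# extended conformations; user-replaceable.
angle	energy
0.0000000000	8.8200000000
0.0490873852	8.4124851070
0.0981747704	8.0146084995
0.1472621556	7.6263701776
0.1963495408	7.2477701412
0.2454369261	6.8788083904
0.2945243113	6.5194849252
0.3436116965	6.1697997454
0.3926990817	5.8297528513
0.4417864669	5.4993442426
0.4908738521	5.1785739196
0.5399612373	4.8674418820
0.5890486225	4.5659481300
0.6381360078	4.2740926636
0.6872233930	3.9918754827
0.7363107782	3.7192965874
0.7853981634	3.4563559776
0.8344855486	3.2030536534
0.8835729338	2.9593896147
0.9326603190	2.7253638615
0.9817477042	2.5009763939
1.0308350895	2.2862272119
1.0799224747	2.0811163154
1.1290098599	1.8856437044
1.1780972451	1.6998093790
1.2271846303	1.5236133391
1.2762720155	1.3570555848
1.3253594007	1.2001361161
1.3744467859	1.0528549328
1.4235341712	0.9152120352
1.4726215564	0.7872074231
1.5217089416	0.6688410965
1.5707963268	0.5601130555
1.6198837120	0.4610233000
1.6689710972	0.3715718301
1.7180584824	0.2917586457
1.7671458676	0.2215837469
1.8162332529	0.1610471336
1.8653206381	0.1101488058
1.9144080233	0.0688887636
1.9634954085	0.0372670070
2.0125827937	0.0152835359
2.0616701789	0.0029383504
2.1107575641	0.0002314504
2.1598449493	0.0071628359
2.2089323346	0.0237325070
2.2580197198	0.0499404637
2.3071071050	0.0857867059
2.3561944902	0.1312712336
2.4052818754	0.1863940469
2.4543692606	0.2511551457
2.5034566458	0.3255545301
2.5525440310	0.4095922001
2.6016314163	0.5032681555
2.6507188015	0.6065823966
2.6998061867	0.7195349232
2.7488935719	0.8421257353
2.7979809571	0.9743548330
2.8470683423	1.1162222162
2.8961557275	1.2677278850
2.9452431127	1.4288718393
2.9943304980	1.5996540791
3.0434178832	1.7800746046
3.0925052684	1.9701334155
3.1415926536	2.1698305120
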