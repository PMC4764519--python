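# Tabulated backbone torsion potential (periodic).
# columns: dihedral (rad), energy (kJ/mol); minimum at trans.
angle	energy
-3.1415926536	0.0000000000
-3.0543261910	0.0038053019
-2.9670597284	0.0151922470
-2.8797932658	0.0340741737
-2.7925268032	0.0603073792
-2.7052603406	0.0936922130
-2.6179938780	0.1339745962
-2.5307274154	0.1808479557
-2.4434609528	0.2339555569
-2.3561944902	0.2928932188
-2.2689280276	0.3572123903
-2.1816615650	0.4264235636
-2.0943951024	0.5000000000
-2.0071286398	0.5773817383
-1.9198621772	0.6579798567
-1.8325957146	0.7411809549
-1.7453292520	0.8263518223
-1.6580627894	0.9128442573
-1.5707963268	1.0000000000
-1.4835298642	1.0871557427
-1.3962634016	1.1736481777
-1.3089969390	1.2588190451
-1.2217304764	1.3420201433
-1.1344640138	1.4226182617
-1.0471975512	1.5000000000
-0.9599310886	1.5735764364
-0.8726646260	1.6427876097
-0.7853981634	1.7071067812
-0.6981317008	1.7660444431
-0.6108652382	1.8191520443
-0.5235987756	1.8660254038
-0.4363323130	1.9063077870
-0.3490658504	1.9396926208
-0.2617993878	1.9659258263
-0.1745329252	1.9848077530
-0.0872664626	1.9961946981
0.0000000000	2.0000000000
0.0872664626	1.9961946981
0.1745329252	1.9848077530
0.2617993878	1.9659258263
0.3490658504	1.9396926208
0.4363323130	1.9063077870
0.5235987756	1.8660254038
0.6108652382	1.8191520443
0.6981317008	1.7660444431
0.7853981634	1.7071067812
0.8726646260	1.6427876097
0.9599310886	1.5735764364
1.0471975512	1.5000000000
1.1344640138	1.4226182617
1.2217304764	1.3420201433
1.3089969390	1.2588190451
1.3962634016	1.1736481777
1.4835298642	1.0871557427
1.5707963268	1.0000000000
1.6580627894	0.9128442573
1.7453292520	0.8263518223
1.8325957146	0.7411809549
1.9198621772	0.6579798567
2.0071286398	0.5773817383
2.0943951024	0.5000000000
2.1816615650	0.4264235636
2.2689280276	0.3572123903
2.3561944902	0.2928932188
2.4434609528	0.2339555569
2.5307274154	0.1808479557
2.6179938780	0.1339745962
2.7052603406	0.0936922130
2.7925268032	0.0603073792
2.8797932658	0.0340741737
2.9670597284	0.0151922470
3.0543261910	0.0038053019
3.1415926536	0.0000000000
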