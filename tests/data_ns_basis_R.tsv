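6	0	0	0	0	0	0	0	0	0	0	0	0.0537639567	-0.1971345081	0.1433705513
6.5	0	0	0	0	0	0	0	0	0	0	0	0	0	0
7.3	0.0130909091	0	0	0	0	0	0	0	0	0	0	-0.0808609909	0.2964903001	-0.2156293092
8.5	0.2045454545	0	0	0	0	0	0	0	0	0	0	-0.1344098919	0.4928362702	-0.3584263783
9.1	0.4221703636	0.007776	0	0	0	0	0	0	0	0	0	-0.1086644835	0.3984364397	-0.2897719561
10.4	0.65506425	0.2450946667	0.0004573333	0	0	0	0	0	0	0	0	-0.0201856626	0.0740140963	-0.0538284337
12	0.1215	0.6571666667	0.2211666667	0.0001666667	0	0	0	0	0	0	0	0	0	0
14.25	0	0.0277291667	0.5097291667	0.4473541667	0.0151875	0	0	0	0	0	0	0	0	0
16.1	0	0	0.0141973333	0.4408746667	0.5156586667	0.0292693333	0	0	0	0	0	0	0	0
17.8	0	0	0	0.012348	0.4278226667	0.5273106667	0.0325186667	0	0	0	0	0	0	0
20.5	0	0	0	0	0	0.0853333333	0.6306666667	0.2826666667	0.0013333333	0	0	0	0	0
23.1	0	0	0	0	0	0	0.002304	0.3085546667	0.6159786667	0.0731626667	0	0	0	0
26	0	0	0	0	0	0	0	0	0.0208333333	0.4791666667	0.4759615385	0.0229232752	0.0040890167	-0.0029738303
27.2	0	0	0	0	0	0	0	0	0	0.079092	0.5783614615	0.3233963125	0.0591258287	-0.0399756027
28.5	0	0	0	0	0	0	0	0	0	0	0.0865384615	0.5650277557	0.2359238699	0.1125099128
29.4	0	0	0	0	0	0	0	0	0	0	8.65385e-05	-0.0357597145	0.4304266455	0.6052465305
30	0	0	0	0	0	0	0	0	0	0	0	-0.5644329897	0.5695876289	0.9948453608
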