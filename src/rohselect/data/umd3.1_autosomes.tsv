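chrom	length
1	158337067
2	137060424
3	121430405
4	120829699
5	121191424
6	119458736
7	112638659
8	113384836
9	105708250
10	104305016
11	107310763
12	91163125
13	84240350
14	84648390
15	85296676
16	81724687
17	75158596
18	66004023
19	64057457
20	72042655
21	71599096
22	61435874
23	52530062
24	62714930
25	42904170
26	51681464
27	45407902
28	46312546
29	51505224
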