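balancer	inversion	chrom	bands	five_prime	three_prime	delta	affected
TM3	In(3LR)sep	3L	65D2-3	6925034	6926125	-1090	Intergenic
TM3	In(3LR)sep	3R	85F2-4	9943831	9944040	-208	Glut4EF
TM3	Unnamed-71B	3L	71B6	15150269	15150272	-2	FucTA
TM3	Unnamed-71B	3R	94D10	23050763	23050764	0	p53
TM3	Unnamed-76B	3L	76B1	19386273	19388151	-1877	CG32206,ms(3)76Ba
TM3	Unnamed-76B	3R	92F4	20637930	20637930	1	Lrrk
TM3	Unnamed-79F	3L	79F3	22637876	22637952	-75	CG14459
TM3	Unnamed-79F	3R	100D1	31653695	31653707	-11	kek6
TM6	In(3LR)P88	3L	61A1-2	97494	97495	0	Intergenic
TM6	In(3LR)P88	3L	61A1-2	263127	263132	-4	Tudor-SN
TM6	In(3LR)P88	3R	89C2-4	16383781	16383775	7	ss
TM6,TM6B	In(3LR)M6	3L	75C	18693657	18693663	-5	CR43987
TM6,TM6B	In(3LR)M6	3R	94A	22393827	22393828	0	CG13857
TM6,TM6B	In(3L)P	3L	63B8-11	3173046	3173053	-6	CG14964
TM6,TM6B	In(3L)P	3L	72E1-2	16308841	16308845	-3	Intergenic
TM6B	In(3LR)HR33	3L	61A1-2	233562	233565	-2	Intergenic
TM6B	In(3LR)HR33	3R	87B2-4	12227473	12227471	3	Intergenic
TM6B	In(3R)Hu	3R	86C5-6	10742047	10742076	-28	TkR86C
TM6B	In(3R)Hu	3R	84F1-2	8287181	8287183	-1	CR44318
TM6B	In(3R)Hu	3R	84B3-6	7048580	7048586	-5	Intergenic
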