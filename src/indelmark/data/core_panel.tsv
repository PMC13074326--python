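# Published 24-marker core fingerprinting panel (2-3 biallelic high-PIC
# markers per chromosome). Order defines the fingerprint digit positions.
Order	Marker	Chromosome
1	T1M0546	Ch01
2	T1M6565	Ch01
3	T2M0112	Ch02
4	T2M3180	Ch02
5	T3M5319	Ch03
6	T4M0210	Ch04
7	T4M6000	Ch04
8	T5M0701	Ch05
9	T5M1237	Ch05
10	T5M2207	Ch05
11	T6M3024	Ch06
12	T6M3582	Ch06
13	T7M0019	Ch07
14	T7M5397	Ch07
15	T8M2758	Ch08
16	T8M5194	Ch08
17	T9M0714	Ch09
18	T9M0982	Ch09
19	TaM0641	Ch10
20	TaM6451	Ch10
21	TbM0724	Ch11
22	TbM1162	Ch11
23	TbM3021	Ch11
24	TcM0679	Ch12
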