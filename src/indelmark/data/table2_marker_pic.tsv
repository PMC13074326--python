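# Published allele number and polymorphism information content (PIC) of the
# 63 core tomato InDel markers scored across 52 germplasm accessions.
Chromosome	Marker	AlleleNumber	PIC
Ch01	T1M0546	3	0.390
Ch01	T1M3899	2	0.355
Ch01	T1M4575	2	0.298
Ch01	T1M5533	3	0.402
Ch01	T1M6009	2	0.307
Ch01	T1M6565	2	0.258
Ch02	T2M0112	2	0.134
Ch02	T2M1114	2	0.074
Ch02	T2M3180	2	0.124
Ch02	T2M3592	2	0.373
Ch02	T2M4420	2	0.145
Ch02	T2M5113	2	0.284
Ch03	T3M0497	2	0.378
Ch03	T3M5319	2	0.359
Ch03	T3M5408	3	0.376
Ch04	T4M0210	2	0.368
Ch04	T4M2158	2	0.384
Ch04	T4M4727	2	0.384
Ch04	T4M6000	2	0.384
Ch05	T5M0251	2	0.299
Ch05	T5M0701	2	0.285
Ch05	T5M1237	2	0.357
Ch05	T5M1244	2	0.358
Ch05	T5M1709	2	0.291
Ch05	T5M2207	2	0.356
Ch05	T5M3207	2	0.090
Ch05	T5M3712	2	0.280
Ch05	T5M4208	2	0.344
Ch05	T5M4704	2	0.356
Ch06	T6M1523	2	0.295
Ch06	T6M3024	2	0.194
Ch06	T6M3003	2	0.193
Ch06	T6M3582	2	0.309
Ch06	T6M3953	2	0.232
Ch06	T6M4626	2	0.383
Ch07	T7M0019	2	0.038
Ch07	T7M0756	2	0.201
Ch07	T7M1005	2	0.111
Ch07	T7M5397	2	0.185
Ch08	T8M2758	2	0.143
Ch08	T8M3706	2	0.186
Ch08	T8M5194	2	0.141
Ch09	T9M0714	2	0.299
Ch09	T9M0982	2	0.138
Ch09	T9M1163	2	0.368
Ch09	T9M2159	2	0.299
Ch09	T9M3154	2	0.299
Ch09	T9M3515	2	0.304
Ch09	T9M3926	2	0.299
Ch09	T9M4118	2	0.299
Ch09	T9M4314	2	0.299
Ch09	T9M4940	2	0.299
Ch09	T9M5137	2	0.309
Ch10	TaM0641	2	0.375
Ch10	TaM6127	2	0.382
Ch10	TaM6451	2	0.286
Ch11	TbM0488	2	0.128
Ch11	TbM0724	2	0.368
Ch11	TbM1162	2	0.357
Ch11	TbM2541	2	0.299
Ch11	TbM3021	2	0.376
Ch12	TcM0679	2	0.306
Ch12	TcM6300	2	0.172
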