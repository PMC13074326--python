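# Published 24-digit DNA fingerprints of 52 tomato germplasm accessions
# (band codes 0-4 over the 24-marker core panel, in panel order).
# Rows appear in the published order (note T44 is printed before T43).
Accession	Fingerprint
T1	111111111111311111111111
T2	111131111111231111111211
T3	111131011111231111211011
T4	212212122212221111112121
T5	212232122212221111220331
T6	210232122212221111122122
T7	222231122212221111212121
T8	412232022212221111102122
T9	410232122212221111102122
T10	212231121112221111210211
T11	212232122222221120111121
T12	212231121112231210121122
T13	212232121112221211212212
T14	212232121111221111210211
T15	212232122202221111112122
T16	212231121122201122022121
T17	212221121112222121112122
T18	220032122212221111111121
T19	212232121122231211111212
T20	210232122212221121121121
T21	210231220111221111111121
T22	212231221111221111111211
T23	322221211111222112112211
T24	212221221111221111111121
T25	212231221111221111111121
T26	210222211112230110212211
T27	212231221111221111111211
T28	212231221112221111211211
T29	422231222202221111210121
T30	012231211112231111112211
T31	210231221111221111111211
T32	222221221112231121211211
T33	422221211102231110222121
T34	422221211112231111212311
T35	212231211112221120112211
T36	422231111111221121202121
T37	212232122212221111210001
T38	212231122222221121022121
T39	212231121112221111211212
T40	222221121122221111211122
T41	010231221112221111211011
T42	422201211112231111212121
T44	212231221112221111121121
T43	212232222212221211211120
T45	012222222202222112211212
T46	212221222212221111212121
T47	210222221322222111221121
T48	212022022212221121201121
T49	210032022212221121211331
T50	212020022212221111111122
T51	212222020102221121121212
T52	212230021112221111211122
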