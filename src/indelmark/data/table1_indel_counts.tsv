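# Published per-chromosome InDel counts from the five-variety tomato genome comparison.
# Columns: Chromosome, Insertion, Deletion, Total, InDel/% (share of the genome-wide total).
Chromosome	Insertion	Deletion	Total	InDel_pct
Chr01	7498	13648	21146	7.40
Chr02	8052	13766	21818	7.63
Chr03	12137	14721	26858	9.40
Chr04	11579	15166	26745	9.36
Chr05	11378	14644	26022	9.11
Chr06	7865	12458	20323	7.11
Chr07	11313	14316	25629	8.97
Chr08	10758	14980	25738	9.01
Chr09	12544	14534	27078	9.47
Chr10	10925	13165	24090	8.43
Chr11	8542	11011	19553	6.84
Chr12	9342	11454	20796	7.28
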