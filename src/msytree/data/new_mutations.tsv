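SNP	Y-Position	Mutation	Forward Primer	Reverse Primer
V2	6778215	A to C	TTGCTGAGTGTACTGGGATCTT	AAGACACCCCAGTTGTCATTTC
V3	6778229	T to C	TTGCTGAGTGTACTGGGATCTT	AAGACACCCCAGTTGTCATTTC
V11	6892902	A to T	CTGGCCTTAGGAAATAGGTCAA	AGGGTCATTATCGTTGAGGAAG
V33	6894717	G to T	AACACCAGGATTTGTTTTGGAG	TTCAGCAACACTGTAGAATCAGG
V34	6894718	C to T	AACACCAGGATTTGTTTTGGAG	TTCAGCAACACTGTAGAATCAGG
V37	6818279	G to A	ATTATTTGAATGCAAGTGGGGA	TGAAACTGAATTAAAGGAAGGTGG
V73	16691696	A to G	TGAAGGAGATTTAATTGGGGTAGA	TTTCCATACCATGCCTTTCTTT
V87	17947454	A to T	CATCCCTTGGTCATCCCTC	CTAGACCCTGATTCATGTAAGCC
V147	6739492	G to A	GTTTTGTGGGTGAGAGAGGAAG	CCATTTCTACATGGAGGAAGTTTT
V248	7589991	C to T	GGCAGCCCTCAGGATATGTA	GATTCCACTAAACCCGACGA
V249	25207704; 26841450;27120952	T/T/T toG/G/G	GGCCAAATCAGAGAAATGGA	CGCAGAACCTGAAATTGTGA
V254	6870497	G to A	AAATGCAGTGTTCCAGGGAGT	TTAAGTAGCTCCCGAGAAGTTAAAG
V262	6659209	C to G	CTACAACGCCCAGCTGATTT	CTGTCTTATGGCCACCCAAG
V265	6661164	A to G	CTCTAGCAATTAGGGCTTCAG	TGTTGCCTAGATGACAAGCA
V303	2798066 - 2798068	del TTT	GGCACCCTGTAGAACCCATA	GAAAAAGAGCAGGCATGGTG
V304	2796955 - 2796957	del GAA	GCTTTGGGGGAGTTAGGAAA	TACAGGGTGCCAGATGGACT
V305	2854573	T to C	ACCCCTGGGTTCAACTATCC	ATTACTCAGGGGTGGTGACG
V306	7594967	G to C	CCTTAAAGGGCTCGGAGAGA	CACTCGACATCGACCTCTCA
V313	7622390	G to A	GAGACTCAGGCAGGCATCAT	TCCAAAGGTTCACAGCTGATT
V314	7642949	A to T	AGGCCTCATCCAGACCTATG	CCACCATGCTGGCTTATTTT
V317	2908553	G to A	AAGATGCCAGCCTCGAGTTA	TTTTTGATCTGAGGCCCATC
V341	4840884	A to T	TTCAGCTATTGCCTTCTATGG	TTTAAGCTCGTGGGAAATGC
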