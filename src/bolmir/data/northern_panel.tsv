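name	sequence	length	reads
bol-miR9408	GTTTCATCTTAGAGAATGTTGTC	23	58
bol-miR9409	TTTTGTTCATGACTGCATTTTC	22	218
bol-miR9410	TACTTAATTATAAGTCGTCTGG	22	1681
bol-miR9411	TACTGGACGACTTACACGGAAG	22	420
bol-miR172a	AGAAUCUUGAUGAUGCUGCAU	21	67605
bol-miR157a	UUGACAGAAGAUAGAGAGCAC	21	170940
bna-miR166a	UCGGACCAGGCUUCAUUCCCC	21	495299
bra-miR167a	UGAAGCUGCCAGCAUGAUCUA	21	684250
bol-miR168c	UCGCUUGGUGCAGGUCGGGAA	21	128281
bol-miR169k*	GGCAAGUUGUCCUUCGGCUACA	22	78
bol-miR1885	CAUCAAUGAAAGGUAUGAUUCC	22	43
bol-miR403	UUAGAUUCACGCACAAACUCG	21	2170
bol-miR397a	UCAUUGAGUGCAGCGUUGAUGU	22	1628
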