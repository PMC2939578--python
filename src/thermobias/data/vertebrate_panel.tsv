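species	class	group	temperature	erk	pct_at_rich	pct_gc_rich
Mus musculus	Mammalia	endotherm	36.9	-16.32	23.22	24.56
Rattus norvegicus	Mammalia	endotherm	37.3	-16.27	22.82	24.91
Human	Mammalia	endotherm	37	-16.11	23.82	24.31
Bos taurus	Mammalia	endotherm	38	-15.97	23.14	25.00
Gallus gallus	Birds	endotherm	39	-16.01	23.59	24.83
Anolis carolinensis	Reptilia	ectotherm	26 (24- 28)	-17.03	23.75	24.45
Xenopus laevis	Amphibia	ectotherm	21(18-22)	-16.53	25.29	22.52
Xenopus tropicalis	Amphibia	ectotherm	25 (23-28)	-16.53	25.22	22.72
Danio rerio	Fish	ectotherm	28.5	-16.76	23.85	23.45
Tetraodon nigroviridis	Fish	ectotherm	27(25-28)	-16.53	25.22	22.72
Takifugu rubripes	Fish	ectotherm	25(23-26)	-17.17	23.31	23.8
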