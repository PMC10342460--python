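gene	rsid	phenotypes	risk_allele
GIPR	rs10423928	twl_nadir,twl_6y	A
DPPIV	rs1861975	twl_nadir,twl_6y	A
NPY1R	rs9764	twl_nadir	T
NPY5R	rs11100493	twl_6y	T
CLOCK	rs1801260	twl_6y,wr_mwl	A
GLP1R	rs10305439	twl_6y,wr_mwl	C
GLP1R	rs2143734	twl_6y	G
GLP1R	rs877446	wr_mwl	A
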