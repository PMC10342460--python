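gene	rsid	ref	alt	maf
GHSR	rs572169	C	T
WFS1	rs10010131	A	G
BDNF	rs6265	C	T
MC4R	rs17782313	T	C
GIPR	rs10423928	T	A
DPPIV	rs17759529	C	T
DPPIV	rs2389643	C	T
DPPIV	rs2268889	C	T
DPPIV	rs12995983	T	C
DPPIV	rs3788979	C	T
DPPIV	rs741529	G	A
DPPIV	rs12469968	G	A
DPPIV	rs1861975	A	G
NPY2R	rs6849115	T	C
NPY2R	rs11099992	A	G
NPY2R	rs6857715	C	T
NPY2R	rs1047214	C	T
NPY2R	rs17304901	G	A
NPY2R	rs11728843	G	A
NPY1R	rs9764	T	C
NPY1R	rs7687423	A	G
NPY1R	rs11100489	T	C
NPY5R	rs11100493	T	C
NPY5R	rs4632602	C	T
NPY5R	rs11724320	T	C
NPY5R	rs7678265	C	T
CLOCK	rs3749474	C	T
CLOCK	rs1801260	A	G
CLOCK	rs4580704	G	A
GLP1R	rs10305439	C	T
GLP1R	rs2143734	A	G
GLP1R	rs877446	A	G
GLP1R	rs6923761	G	A
GLP1R	rs932443	T	C
GLP1R	rs2300612	T	C
GLP1R	rs2268640	G	A
TCF7L2	rs7903146	C	T
TCF7L2	rs12255372	G	A
KCNJ11	rs5215	C	T
KCNJ11	rs5218	G	A
KCNJ11	rs5219	T	C
KCNJ11	rs886288	A	G
FTO	rs9939609	T	A
FTO	rs9939973	G	A
PYY	rs2700831	T	C
PYY	rs9890045	G	A
PYY	rs1684668	T	C
PYY	rs1618809	A	G
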