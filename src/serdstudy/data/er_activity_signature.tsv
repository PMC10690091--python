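# Illustrative ER-activity signature (synthetic placeholder).
# Well-known estrogen-responsive genes with plausible directions,
# provided so the scoring machinery has a worked input; it is NOT a
# curated or published signature. Edit freely or supply your own.
gene	direction
GREB1	1
PGR	1
TFF1	1
MYB	1
IGFBP4	1
CA12	1
SGK3	1
RET	1
NRIP1	1
CCND1	1
FOXM1	1
ANXA9	1
SLC39A6	1
ELOVL2	1
RARA	1
CXCL12	-1
IL1R1	-1
TGFB2	-1
CDKN1A	-1
SOX4	-1
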