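# synonym	canonical
# Canonical vocabulary: 13 protein-coding genes, 2 rRNAs, 22 tRNAs of the
# animal mitochondrial genome. Lookup is case-insensitive with spaces and
# hyphens collapsed; edit freely to add local naming conventions.
COX1	COX1
COI	COX1
CO1	COX1
COXI	COX1
CYTOCHROME C OXIDASE SUBUNIT I	COX1
CYTOCHROME C OXIDASE SUBUNIT 1	COX1
COX2	COX2
COII	COX2
CO2	COX2
COXII	COX2
CYTOCHROME C OXIDASE SUBUNIT II	COX2
CYTOCHROME C OXIDASE SUBUNIT 2	COX2
COX3	COX3
COIII	COX3
CO3	COX3
COXIII	COX3
CYTOCHROME C OXIDASE SUBUNIT III	COX3
CYTOCHROME C OXIDASE SUBUNIT 3	COX3
CYTB	CYTB
COB	CYTB
CYB	CYTB
CYTOCHROME B	CYTB
ND1	ND1
NAD1	ND1
NADH1	ND1
NADH DEHYDROGENASE SUBUNIT 1	ND1
ND2	ND2
NAD2	ND2
NADH2	ND2
NADH DEHYDROGENASE SUBUNIT 2	ND2
ND3	ND3
NAD3	ND3
NADH3	ND3
NADH DEHYDROGENASE SUBUNIT 3	ND3
ND4	ND4
NAD4	ND4
NADH4	ND4
NADH DEHYDROGENASE SUBUNIT 4	ND4
ND4L	ND4L
NAD4L	ND4L
NADH4L	ND4L
NADH DEHYDROGENASE SUBUNIT 4L	ND4L
ND5	ND5
NAD5	ND5
NADH5	ND5
NADH DEHYDROGENASE SUBUNIT 5	ND5
ND6	ND6
NAD6	ND6
NADH6	ND6
NADH DEHYDROGENASE SUBUNIT 6	ND6
ATP6	ATP6
ATPASE6	ATP6
ATPASE 6	ATP6
ATP SYNTHASE F0 SUBUNIT 6	ATP6
ATP8	ATP8
ATPASE8	ATP8
ATPASE 8	ATP8
ATP SYNTHASE F0 SUBUNIT 8	ATP8
RRNL	rrnL
16S	rrnL
16S RRNA	rrnL
16S RIBOSOMAL RNA	rrnL
L-RRNA	rrnL
LARGE SUBUNIT RIBOSOMAL RNA	rrnL
RRN16	rrnL
RRNS	rrnS
12S	rrnS
12S RRNA	rrnS
12S RIBOSOMAL RNA	rrnS
S-RRNA	rrnS
SMALL SUBUNIT RIBOSOMAL RNA	rrnS
RRN12	rrnS
TRNA	trnA
TRNA-ALA	trnA
TRNC	trnC
TRNA-CYS	trnC
TRND	trnD
TRNA-ASP	trnD
TRNE	trnE
TRNA-GLU	trnE
TRNF	trnF
TRNA-PHE	trnF
TRNG	trnG
TRNA-GLY	trnG
TRNH	trnH
TRNA-HIS	trnH
TRNI	trnI
TRNA-ILE	trnI
TRNK	trnK
TRNA-LYS	trnK
TRNL1	trnL1
TRNA-LEU(CUN)	trnL1
TRNL(CUN)	trnL1
TRNL2	trnL2
TRNA-LEU(UUR)	trnL2
TRNL(UUR)	trnL2
TRNM	trnM
TRNA-MET	trnM
TRNN	trnN
TRNA-ASN	trnN
TRNP	trnP
TRNA-PRO	trnP
TRNQ	trnQ
TRNA-GLN	trnQ
TRNR	trnR
TRNA-ARG	trnR
TRNS1	trnS1
TRNA-SER(AGN)	trnS1
TRNS(AGN)	trnS1
TRNS2	trnS2
TRNA-SER(UCN)	trnS2
TRNS(UCN)	trnS2
TRNT	trnT
TRNA-THR	trnT
TRNV	trnV
TRNA-VAL	trnV
TRNW	trnW
TRNA-TRP	trnW
TRNY	trnY
TRNA-TYR	trnY
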