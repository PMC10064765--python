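# mitocompare gene-name canonicalization table, v1
# alias<TAB>canonical  (aliases matched case-insensitively)
COX1	cox1
COXI	cox1
cox-1	cox1
COX2	cox2
COXII	cox2
cox-2	cox2
COX3	cox3
COXIII	cox3
cox-3	cox3
COB	cob
cytb	cob
cyt_b	cob
CYTB	cob
ATP6	atp6
ATPase6	atp6
ATP8	atp8
ATPase8	atp8
ATP9	atp9
ATPase9	atp9
NAD1	nad1
ND1	nad1
NAD2	nad2
ND2	nad2
NAD3	nad3
ND3	nad3
NAD4	nad4
ND4	nad4
nad4l	nad4L
NAD4L	nad4L
ND4L	nad4L
NAD5	nad5
ND5	nad5
NAD6	nad6
ND6	nad6
RPS3	rps3
rps-3	rps3
RNL	rnl
LSU	rnl
rrnL	rnl
l-rRNA	rnl
large_subunit_ribosomal_RNA	rnl
RNS	rns
SSU	rns
rrnS	rns
s-rRNA	rns
small_subunit_ribosomal_RNA	rns
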