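gene	ensembl	r
PGD	ENSG00000142657	-0.81
CBX5	ENSG00000094916	0.7
SET	ENSG00000119335	0.65
NUP62	ENSG00000213024	0.63
PFDN2	ENSG00000143256	0.62
SMARCD1	ENSG00000066117	-0.62
CCT4	ENSG00000115484	0.61
CCT2	ENSG00000166226	0.60
GTF2F2	ENSG00000188342	0.59
EIF3E	ENSG00000104408	0.59
SLC39A6	ENSG00000141424	-0.59
SEZ6	ENSG00000063015	-0.58
BTG3	ENSG00000154640	0.57
MYCN	ENSG00000134323	0.57
ODC1	ENSG00000115758	0.57
ANTXR2	ENSG00000163297	0.56
BCL10	ENSG00000142867	0.56
CCT3	ENSG00000163468	0.56
MYL12A	ENSG00000101608	0.56
SERBP1	ENSG00000142864	0.56
NR4A2	ENSG00000153234	0.55
IGSF9	ENSG00000085552	0.55
PTPRS	ENSG00000105426	-0.54
PHF5A	ENSG00000100410	0.54
RSL1D1	ENSG00000171490	0.54
ARF4	ENSG00000168374	0.54
NFIL3	ENSG00000165030	0.54
SEC61A1	ENSG00000058262	0.53
PSMA2	ENSG00000106588	0.53
DNAJB5	ENSG00000137094	0.53
GDI2	ENSG00000057608	0.53
NFIB	ENSG00000147862	-0.53
LMO3	ENSG00000048540	-0.53
RPL11	ENSG00000142676	-0.52
NA	ENSG00000155130	0.52
DACT1	ENSG00000165617	0.52
KDM6B	ENSG00000132510	0.52
NPM1	ENSG00000181163	0.51
CDK8	ENSG00000132964	-0.51
OBSCN	ENSG00000154358	-0.51
ING1	ENSG00000153487	0.50
RBM7	ENSG00000076053	0.50
MTHFD2	ENSG00000065911	0.50
BAZ1A	ENSG00000198604	0.50
SEC11A	ENSG00000140612	0.50
MMP24	ENSG00000125966	-0.50
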