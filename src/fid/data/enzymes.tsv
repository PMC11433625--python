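# Starter panel of common commercial restriction endonucleases.
# Columns: name<TAB>recognition site with ^ marking the top-strand cut.
# Slash-joined names are site-isoschizomer groups sharing a recognition site.
AluI	AG^CT
HaeIII	GG^CC
HinfI	G^ANTC
CfoI/HhaI/HinP1I	GCG^C
MseI	T^TAA
RsaI	GT^AC
TaqI	T^CGA
Sau3AI	^GATC
MspI	C^CGG
DdeI	C^TNAG
Fnu4HI	GC^NGC
Cac8I	GCN^NGC
BfaI	C^TAG
NlaIII	CATG^
NlaIV	GGN^NCC
EcoRI	G^AATTC
HindIII	A^AGCTT
StuI	AGG^CCT
MfeI	C^AATTG
SpeI	A^CTAGT
NcoI	C^CATGG
AvaII	G^GWCC
AvaI	C^YCGRG
StyI	C^CWWGG
Hpy8I	GTN^NAC
HpyCH4VI/MaeII/TaiI	A^CGT
FaiI	YA^TR
DraI	TTT^AAA
EcoRV	GAT^ATC
XbaI	T^CTAGA
PstI	CTGCA^G
KpnI	GGTAC^C
BamHI	G^GATCC
ApaI	GGGCC^C
TauI	GCSG^C
XmaIII	C^GGCCG
SduI	GDGCH^C
CauII	CC^SGG
Hpy188I	TCN^GA
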