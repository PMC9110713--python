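# Default verification-digest enzyme list: common palindromic 6/8-cutters.
# Replaceable: same TSV format (name, IUPAC site, cut_top, cut_bottom),
# cut offsets counted from each strand's own 5' side of the site.
name	site	cut_top	cut_bottom
EcoRI	GAATTC	1	1
BamHI	GGATCC	1	1
HindIII	AAGCTT	1	1
XhoI	CTCGAG	1	1
SalI	GTCGAC	1	1
XbaI	TCTAGA	1	1
SpeI	ACTAGT	1	1
NheI	GCTAGC	1	1
NcoI	CCATGG	1	1
BglII	AGATCT	1	1
MluI	ACGCGT	1	1
AflII	CTTAAG	1	1
AgeI	ACCGGT	1	1
PciI	ACATGT	1	1
NdeI	CATATG	2	2
ClaI	ATCGAT	2	2
EcoRV	GATATC	3	3
SmaI	CCCGGG	3	3
PvuII	CAGCTG	3	3
ScaI	AGTACT	3	3
StuI	AGGCCT	3	3
HpaI	GTTAAC	3	3
SspI	AATATT	3	3
DraI	TTTAAA	3	3
ApaI	GGGCCC	5	5
KpnI	GGTACC	5	5
SacI	GAGCTC	5	5
SphI	GCATGC	5	5
PstI	CTGCAG	5	5
NsiI	ATGCAT	5	5
NotI	GCGGCCGC	2	2
AscI	GGCGCGCC	2	2
PacI	TTAATTAA	5	5
PmeI	GTTTAAAC	4	4
SbfI	CCTGCAGG	6	6
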