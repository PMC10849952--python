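# halomet isotope constants, version 2026.1
# Monoisotopic masses (Da) and natural abundances for the supported element set.
# D is deuterium treated as a distinct, isotopically pure element so that
# labelled formulas (e.g. C28H53D2O8Cl) can be handled by ordinary formula
# arithmetic. Values follow standard reference atomic data (CODATA/IUPAC).
# element	mass	abundance
H	1.0078250319	0.999885
H	2.0141017779	0.000115
D	2.0141017779	1.0
C	12.0	0.9893
C	13.0033548378	0.0107
N	14.0030740052	0.99636
N	15.0001088984	0.00364
O	15.9949146221	0.99757
O	16.9991315	0.00038
O	17.9991604	0.00205
S	31.97207069	0.9499
S	32.9714585	0.0075
S	33.96786683	0.0425
S	35.96708088	0.0001
Cl	34.96885271	0.7576
Cl	36.96590260	0.2424
Na	22.98976928	1.0
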