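# Default cis-regulatory element set for promoter scanning.
# Columns: name <TAB> IUPAC consensus <TAB> source tag
# Consensus strings follow IUPAC nucleotide codes; fixed-length repeats may
# be written as X{n}. These are configurable defaults, not measured data:
# verify the ACE/CA-hybrid/CG-hybrid consensus against the primary motif
# literature before biological use.
CArG	CCW{6}GG	MADS/RIN-binding
PBE-box	CACATG	PIF-binding
G-box	CACGTG	PIF/HY5-binding
E-box	CANNTG	bHLH-binding
ACE-motif	ACGTG	HY5-binding
CA-hybrid	GACGTA	HY5-binding
CG-hybrid	GACGTG	HY5-binding
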