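# SYNTHETIC stand-in for a manually curated multi-ancestry skin-pigmentation panel.
# rsIDs are well-known pigmentation-associated variants from the literature; the
# chrom/pos/allele columns are synthetic placeholders, NOT real coordinates.
# Use for exercising the unweighted-score path only.
snp_id	chrom	pos	effect_allele	other_allele	gene
rs16891982	5	33951000	C	G	SLC45A2
rs2675345	15	48426000	G	A	SLC24A5
rs1126809	11	89017000	G	A	TYR
rs12913832	15	28365000	A	G	HERC2
rs1635168	15	28590000	C	A	HERC2
rs7109255	11	88550000	G	A	GRM5
rs6120849	20	33865000	C	T	EDEM2
rs7870409	9	129870000	G	A	RALGPS1
rs4778123	15	27985000	T	C	OCA2
rs9920172	15	28020000	A	G	OCA2
rs644490	15	28080000	T	C	OCA2
rs2153271	9	16864000	T	C	BNC2
rs3758833	11	88070000	A	G	CTSC
rs12203592	6	396000	T	C	IRF4
rs3778607	6	410000	G	A	IRF4
rs1805007	16	89986000	T	C	MC1R
rs12821256	12	89328000	C	T	KITLG
rs1325132	9	12700000	C	T	TYRP1
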