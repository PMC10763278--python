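species	group	protein_coding_genes	p3a_count
Allium cepa	glycophyte	47066	22
Eucalyptus grandis	glycophyte	33352	11
Gossypium raimondii	glycophyte	35609	14
Hordeum vulgare	glycophyte	31448	9
Oryza sativa	glycophyte	28738	10
Phaseolus vulgaris	glycophyte	28134	13
Raphanus sativus	glycophyte	49855	23
Sesamum indicum	glycophyte	24075	16
Solanum lycopersicum	glycophyte	25613	7
Zea mays	glycophyte	34337	13
Aeluropus littoralis	halophyte	15916	10
Beta vulgaris	halophyte	24491	7
Eutrema salsugineum	halophyte	26943	10
Limonium bicolor	halophyte	38444	17
Phoenix dactylifera	halophyte	29239	11
Setaria viridis	halophyte	28032	10
Solanum chilense	halophyte	25885	8
Suaeda aralocaspica	halophyte	29604	9
Zostera marina	halophyte	20450	8
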