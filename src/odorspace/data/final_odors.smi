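# SMILES fixture for the 11 consensus odorants (4 distinctive, 7 non-distinctive).
# Structures curated from public chemical databases, keyed by odorant name and
# CAS registry number; class labels are the final consensus assignments.
# Columns: name<TAB>smiles<TAB>label<TAB>cas
cis-3-hexenol	CC/C=C\CCO	distinctive	928-96-1
methyl salicylate	COC(=O)c1ccccc1O	distinctive	119-36-8
1-butanol	CCCCO	distinctive	71-36-3
cineole	CC12CCC(CC1)C(C)(C)O2	distinctive	470-82-6
benzyl acetate	CC(=O)OCc1ccccc1	nondistinctive	140-11-4
heptanal	CCCCCCC=O	nondistinctive	111-71-7
4-ethyl octanoic acid	CCCCC(CC)CCC(=O)O	nondistinctive	16493-80-4
methional	CSCCC=O	nondistinctive	3268-49-3
isobutyric acid	CC(C)C(=O)O	nondistinctive	79-31-2
4-decanolide	CCCCCCC1CCC(=O)O1	nondistinctive	706-14-9
p-cresol	Cc1ccc(O)cc1	nondistinctive	106-44-5
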