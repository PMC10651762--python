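rule_id	group	name	transformation_type	smirks	notes	reference
R001	Aminophenyl	Aminophenyl_to_aminobicyclo[1.1.1]pentyl	ring substitution	[*:3]-[#7:2](-[*:1])-[c:4]1[c; D2][c; D2][c; D2][c; D2][c; D2]1>>[*:3]-[#7:2](-[*:1])[C:4]12[#6]-[#6](-[#6]1)-[#6]2	metabolic stability;isosteric replacement	B90
R002	1,4-diaminophenyl	1,4-diaminophenyl_to_3,6-diaminopyridazinyl	ring modification	[#7H2:1]-[c; D3:2]1[c; D2:6][c; D2:5][c; D3:4][c; D2:3][c; D2]1>>[#7H2:1]-[c; D3:2]1[c; D2:6][c; D2:5][c; D3:4]nn1	metabolic stability	B103
R003	Carboxyl	Carboxyl_to_2,4-dioxo-1,3-thiazolidin-5-yl (ionized)	ring addition	[#8; D1][#6; A; !R:2]([*:1]) = O>>[*:1]-[#6:2]-1-[#16]-[#6](=O)-[#7-]-[#6]-1 = O |s:0:1|	similar acidic pKa;increased sterics	B38; B25
R004	Benzoylphenyl	benzoylphenyl_to_(3-phenyloxetan-3-yl)phenyl	linker modification	[#6; a:1][C; $([#6:2] = O),$([#6; A; @:2]1[#6]-[#6]-[#6]1),$([#6; H2])][#6; a:3] >>[#6; a:3][#6; A@:2]1([#6; a:1])[#6]-[#8:4]-[#6]1	isosteric replacement;metabolic stability;reduce phototoxicity in benzophenones	B26
R005	Phenyl	Phenyl_to_cyclohexyl	ring substitution	[c; x2:2]1[c; x2:3][c; x2:4][c; x2:5][c; x2:6][c; x2:1]1>>[#6:5]-1-[#6:6]-[#6:1]-[#6:2]-[#6:3]-[#6:4]-1	bioisosteric replacement;increase lipophilicity;improved aqueous solubility;enhanced oral bioavailability;reproducible PK profiles	B79; B80; B43; B92
R006	Phenyl	Phenyl_to_(propoxyimino)methyl	functional group change	[*:3]-[c; x2D3:1]1[c; x2D2][c; x2D2][c; x2D2][c; x2D2][c; x2D2]1>>[#6]-[#6]-[#6]-[#8]\[#7] = [#6:1]\[*:3] |rb:1:2.2:2.3:2.4:2.5:2.6:2,s:1:3|	bioisostere replacement;modulation of selectivity	B78; B92
R007	Phenyl	Phenyl_to_(2-oxopyridin-1(2H)-yl)	ring modification	[c; D2:2]1[c; x2:3][c; x2:4][c; x2:5][c; x2:6][c; D3:1]1>>O = [#6; x2:2]-1-[#7:1]-[#6:6] = [#6:5]-[#6:4] = [#6:3]-1	improved potency;reduce off-target;metabolic stability;enhanced solubility;reduced lipophilicity	B92
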