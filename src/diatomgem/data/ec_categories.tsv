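# Default pathway-category map for EC-based model comparison tallies.
# key_type is "subsystem" (exact, case-insensitive) or "ec_prefix"
# (EC number prefix match, tried when no subsystem rule applies).
key_type	key	category
subsystem	amino acid metabolism	Amino acid metabolism
subsystem	urea cycle	Amino acid metabolism
subsystem	sulfur and cysteine metabolism	Amino acid metabolism
subsystem	nitrogen assimilation	Nitrogen metabolism
subsystem	glycolysis	Carbohydrate metabolism
subsystem	carbohydrate storage	Carbohydrate metabolism
subsystem	pyruvate metabolism	Carbohydrate metabolism
subsystem	TCA cycle	Carbohydrate metabolism
subsystem	anaplerosis	Carbohydrate metabolism
subsystem	malate valve	Carbohydrate metabolism
subsystem	Calvin-Benson-Bassham cycle	Photosynthesis
subsystem	photosynthesis light reactions	Photosynthesis
subsystem	oxidative phosphorylation	Oxidative phosphorylation
subsystem	fatty acid biosynthesis	Lipid metabolism
subsystem	carotenoid and pigment biosynthesis	Pigment metabolism
subsystem	nucleotide biosynthesis	Nucleotide metabolism
ec_prefix	1.10.	Photosynthesis
ec_prefix	1.97.	Photosynthesis
ec_prefix	7.1.	Oxidative phosphorylation
ec_prefix	2.3.1.	Lipid metabolism
ec_prefix	1.	Oxidoreductases (other)
ec_prefix	2.	Transferases (other)
ec_prefix	3.	Hydrolases (other)
ec_prefix	4.	Lyases (other)
ec_prefix	5.	Isomerases (other)
ec_prefix	6.	Ligases (other)
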