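compound_id	name	monoisotopic_mass	pathway_ids
C001	Citrate	192.027003	tca
C002	Succinate	118.026609	tca
C003	Fumarate	116.010959	tca
C004	Malate	134.021523	tca
C005	2-Oxoglutarate	146.021523	tca
C006	Pyruvate	88.016044	tca;glycolysis
C007	D-Glucose	180.063388	glycolysis
C008	L-Lactate	90.031694	glycolysis
C009	L-Alanine	89.047678	amino_acid
C010	L-Glutamine	146.069142	amino_acid
C011	Palmitate	256.240230	fatty_acid
C012	Oleate	282.255880	fatty_acid
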