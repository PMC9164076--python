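ligand	pubchem_id	receptor	binding_energy	hbond_residues	hydrophobic_residues
Loratadine	3957	GRIN2B(PDB:7EU8)	-7.3	N/A	Trp391,Glu163,Tyr164,Asp165,Val390,Tyr389,Asp477,Tyr476,His405,Thr475,Trp166
Fexofenadine	3348	GRIN2B(PDB:7EU8)	-6.8	Trp166,Trp391,Asp165	Ser469,Phe474,Thr475,Tyr476,Val390,Pro435,Tyr164
Triprolidine	5282443	GRIN2B(PDB:7EU8)	-6.7	Arg755	Ala734,Glu531,Leu797,Met789,Phe460,Phe529,Ile530,Glu793,Leu752
Ebastine	3191	GRIN2B(PDB:7EU8)	-6.6	Ile190	Ile691,Gln487,Glu522,Trp498,Asn521,Tyr526,Glu191,Gly196
Dimetindene	21855	GRIN2B(PDB:7EU8)	-6.5	N/A	Leu792,Leu795,Asp463,Asn432,Trp796,Lys458,Thr701,Arg673,Leu699,Glu698
Terfenadine	5405	GRIN2B(PDB:7EU8)	-6.4	N/A	Phe474,Trp166,Val390,Trp391,Pro435,Tyr164,Asp165,Thr433,Thr475,Tyr476
Tripelenamine	5587	GRIN2B(PDB:7EU8)	-5.6	N/A	Leu752,Glu793,Phe529,Ile530,Leu797,Asn737,Ala734,Arg755,Ala794,Glu790
Emedastine	3219	GRIN2B(PDB:7EU8)	-5.5	Trp166	Ser469,Pro435,Phe474,Tyr164,Val434,Thr433,Tyr476
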