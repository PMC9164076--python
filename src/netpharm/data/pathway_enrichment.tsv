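pathway_id	name	genes	rich_factor	fdr	background_size
hsa00220	Arginine biosynthesis	NOS2,NOS3	0.0952	0.0125	21
hsa04720	Long-term potentiation	GRRIN2B,RPS6KA2,RPS6KA2	0.0469	0.0026	64
hsa00330	Arginine and proline metabolism	NOS2,NOS3	0.0417	0.0497	48
hsa04931	Insulin resistance	NOS3,RPS6KA2,RPS6KA2	0.0374	0.0006	
hsa04071	Sphingolipid signaling pathway	NOS3,FYN,S1PR5,OPRD1	0.0345	0.0006	
hsa04714	Thermogenesis	PPARG,RPS6KA2,RPS6KA2	0.0131	0.0497	
hsa04080	Neuroactive ligand-receptor interaction	GRIN2B,OPRM1,OPRD1,S1PR5	0.0121	0.0111	330
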