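pathway_name	source	category
hematopoietic cell lineage (hsa04640)	KEGG	hematopoiesis
complement and coagulation cascades (hsa04610)	KEGG	complement-coagulation
platelet activation (hsa04611)	KEGG	platelet activity
Toll-like receptor signaling (hsa04620)	KEGG	innate immunity
Toll and Imd signaling (hsa04624)	KEGG	innate immunity
NOD-like receptor signaling (hsa04621)	KEGG	innate immunity
RIG-I-like receptor signaling (hsa04622)	KEGG	innate immunity
cytosolic DNA-sensing (hsa04623)	KEGG	innate immunity
C-type lectin receptor signaling (hsa04625)	KEGG	innate immunity
natural killer cell-mediated cytotoxicity (hsa04650)	KEGG	NK cell activity
antigen processing and presentation (hsa04612)	KEGG	antigen presentation
T cell receptor signaling (hsa04660)	KEGG	adaptive immunity
Th1 and Th2 cell differentiation (hsa04658)	KEGG	adaptive immunity
Th17 cell differentiation (hsa04659)	KEGG	adaptive immunity
IL-17 signaling (hsa04657)	KEGG	cytokines-chemokines
B cell receptor signaling (hsa04662)	KEGG	adaptive immunity
Fc epsilon RI signaling (hsa04664)	KEGG	signaling
Fc gamma R-mediated phagocytosis (hsa04666)	KEGG	signaling
leukocyte transendothelial migration (hsa04670)	KEGG	leukocyte migration
intestinal immune network for IgA production (hsa04672)	KEGG	adaptive immunity
chemokine signaling (hsa04062)	KEGG	cytokines-chemokines
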