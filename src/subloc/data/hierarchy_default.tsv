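# Default label layout: 10 organelles x up to 8 suborganellar slots,
# 44 occupied cells in total. Columns: organelle, suborganelle, slot (0-7).
# Suborganelle names follow the UniProt subcellular-location controlled
# vocabulary, fully qualified so every name is unique. This file is data,
# not code: substitute your own layout of the same schema to change the
# class set.
nucleus	nucleolus	0
nucleus	nucleoplasm	1
nucleus	nuclear envelope	2
nucleus	nuclear membrane	3
nucleus	nuclear lamina	4
nucleus	nuclear matrix	5
cytoplasm	cytosol	0
cytoplasm	cytoplasmic granule	1
cytoplasm	cytoskeleton	2
cytoplasm	perinuclear region	3
cytoplasm	cell cortex	4
cytoplasm	stress granule	5
cytoplasm	centrosome	6
extracellular	secreted	0
extracellular	extracellular matrix	1
extracellular	cell surface	2
mitochondrion	mitochondrial matrix	0
mitochondrion	mitochondrial inner membrane	1
mitochondrion	mitochondrial outer membrane	2
mitochondrion	mitochondrial intermembrane space	3
mitochondrion	mitochondrial nucleoid	4
cell membrane	plasma membrane	0
cell membrane	apical cell membrane	1
cell membrane	basolateral cell membrane	2
endoplasmic reticulum	endoplasmic reticulum lumen	0
endoplasmic reticulum	endoplasmic reticulum membrane	1
endoplasmic reticulum	rough endoplasmic reticulum	2
endoplasmic reticulum	sarcoplasmic reticulum	3
plastid	chloroplast envelope	0
plastid	chloroplast stroma	1
plastid	thylakoid lumen	2
plastid	thylakoid membrane	3
plastid	chloroplast membrane	4
Golgi apparatus	cis-Golgi network	0
Golgi apparatus	trans-Golgi network	1
Golgi apparatus	Golgi apparatus membrane	2
Golgi apparatus	Golgi stack membrane	3
lysosome/vacuole	lysosome lumen	0
lysosome/vacuole	lysosome membrane	1
lysosome/vacuole	vacuole lumen	2
lysosome/vacuole	vacuole membrane	3
peroxisome	peroxisomal matrix	0
peroxisome	peroxisome membrane	1
peroxisome	glyoxysome	2
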