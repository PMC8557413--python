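genome	cds_id	pathway	essential_aa
BC	putA	5-Hydroxytryptamine degradation	0
BC	ilvE	Alanine biosynthesis	0
BC	carA-carB	Arginine biosynthesis	1
BC	carB	Arginine biosynthesis	1
BC	atpA	ATP synthesis	0
BC	aroA	Chorismate biosynthesis	1
BC	aroC	Chorismate biosynthesis	1
BC	purA	De novo purine biosynthesis	0
BC	carA-carB	De novo pyrimidine ribonucleotides biosynthesis	0
BC	carB	De novo pyrimidine ribonucleotides biosynthesis	0
BC	hisD	Histidine biosynthesis	1
BC	ilvE	Isoleucine biosynthesis	1
BC	ilvE	Leucine biosynthesis	1
BC	leuC	Leucine biosynthesis	1
BC	ilvE	Lysine biosynthesis	1
BC	lysA	Lysine biosynthesis	1
BC	dapF	Lysine biosynthesis	1
BC	tktA	Pentose phosphate pathway	0
BC	ilvE	Valine biosynthesis	1
DC	argH	Arginine biosynthesis	1
DC	carA	Arginine biosynthesis	1
DC	carB	Arginine biosynthesis	1
DC	atpA	ATP synthesis	0
DC	aroC	Chorismate biosynthesis	1
DC	carA	De novo pyrimidine ribonucleotides biosynthesis	0
DC	carB	De novo pyrimidine ribonucleotides biosynthesis	0
DC	ilvD	Isoleucine biosynthesis	1
DC	leuD	Leucine biosynthesis	1
DC	leuC	Leucine biosynthesis	1
DC	lysC	Lysine biosynthesis	1
DC	tktA	Pentose phosphate pathway	0
DC	lysC	Threonine biosynthesis	1
DC	ilvD	Valine biosynthesis	1
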