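genus	cag
Achromobacter	CAG1
Bacteroides	CAG1
Chloroplast	CAG1
Delftia	CAG1
Enterococcus	CAG1
Escherichia-Shigella	CAG1
Klebsiella	CAG1
Proteus	CAG1
Pseudomonas	CAG1
Actinobacteria_unclassified	CAG1
Enterobacteriaceae_unclassified	CAG1
Lachnospiraceae_unclassified	CAG1
Rhizobiaceae_unclassified	CAG1
Unknown	CAG1
Anaerococcus	CAG2
Campylobacter	CAG2
Eikenella	CAG2
Erysipelatoclostridium	CAG2
Fusobacterium	CAG2
Gemella	CAG2
Granulicatella	CAG2
Leptotrichia	CAG2
Parvimonas	CAG2
Peptostreptococcus	CAG2
Porphyromonas	CAG2
Streptococcus	CAG2
Akkermansia	CAG3
Alistipes	CAG3
Bifidobacterium	CAG3
Blautia	CAG3
Collinsella	CAG3
Dialister	CAG3
Faecalibacterium	CAG3
Holdemanella	CAG3
Parabacteroides	CAG3
Prevotella	CAG3
Subdoligranulum	CAG3
Acinetobacter	CAG4
Aquabacterium	CAG4
Bacillus	CAG4
Chryseobacterium	CAG4
Lactobacillus	CAG4
Ralstonia	CAG4
Caulobacteraceae_unclassified	CAG4
Clostridiaceae_unclassified	CAG4
Peptostreptococcaceae_unclassified	CAG4
Sphingomonadaceae_unclassified	CAG4
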