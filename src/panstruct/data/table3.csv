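variety,bioproject,genome_size_bp,n_contigs,contig_n50_bp,n_gaps,scaffold_n50_bp,busco_raw_pct,busco_adjusted_pct
CHAO MEO::IRGC 80273-1,PRJNA565484,376856903,55,11024768,43,30350168,97.60,98.49
Azucena,PRJNA424001,379627553,28,22940949,16,30954872,97.80,98.69
KETAN NANGKA::IRGC 19961-2,PRJNA564615,380759091,21,22679302,9,30696581,98.00,98.89
ARC 10497::IRGC 12485-1,PRJNA565479,378463869,40,17921520,28,30566713,98.40,99.30
IR 64,PRJNA509165,386698898,104,7352909,92,31218896,95.70,96.57
PR 106::IRGC 53418-1,PRJNA563359,391176105,16,27051416,4,32028703,96.60,97.48
LIMA::IRGC 81487-1,PRJNA564572,392625308,17,27369091,5,32421942,98.50,99.40
KHAO YAI GUANG::IRGC 65972-1,PRJNA565481,393737720,19,21823919,7,32080718,98.60,99.50
GOBOL SAIL (BALAM)::IRGC 26624-2,PRJNA564763,391772995,15,29604901,3,31753752,97.90,98.79
LIU XU::IRGC 109232-1,PRJNA577228,392033263,17,30913760,5,32301089,98.40,99.30
LARHA MUGAD::IRGC 52339-1,PRJNA565480,390195943,16,30747645,4,32107744,98.60,99.50
NATEL BORO::IRGC 34749-1,PRJNA565483,383720936,16,27825079,4,31305988,98.10,98.99
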