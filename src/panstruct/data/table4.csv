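variety,total_pct,ltr_rt_pct,line_pct,sine_pct,dna_te_pct,unclassified_pct
NIPPONBARE,46.07,23.55,1.52,0.41,16.18,4.41
CHAO MEO::IRGC 80273-1,46.25,24.00,1.46,0.40,15.59,4.80
Azucena,47.07,24.48,1.47,0.40,15.82,4.89
KETAN NANGKA::IRGC 19961-2,46.99,24.87,1.47,0.40,15.72,4.53
ARC 10497::IRGC 12485-1,46.95,24.74,1.48,0.40,15.68,4.65
PR 106::IRGC 53418-1,47.95,26.82,1.41,0.39,15.05,4.28
Minghui 63,47.97,26.61,1.44,0.4,15.3,4.22
IR 64,47.87,26.82,1.42,0.40,14.97,4.26
Zhenshan 97,47.95,26.79,1.42,0.39,15.19,4.16
LIMA::IRGC 81487-1,48.04,26.87,1.40,0.39,15.01,4.37
KHAO YAI GUANG::IRGC 65972-1,48.27,27.27,1.40,0.39,14.87,4.34
GOBOL SAIL (BALAM)::IRGC 26624-2,48.15,26.99,1.40,0.39,14.99,4.38
LIU XU::IRGC 109232-1,46.92,27.06,1.26,0.32,14.31,3.97
LARHA MUGAD::IRGC 52339-1,48.05,26.74,1.41,0.39,15.09,4.42
N 22::IRGC 19379-1,47.79,25.95,1.44,0.39,15.20,4.81
NATEL BORO::IRGC 34749-1,47.33,25.75,1.42,0.40,15.12,4.64
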