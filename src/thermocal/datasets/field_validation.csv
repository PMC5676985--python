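label,surface,ref_mean_c,ref_sd_c,orig_mean_c,orig_sd_c,corr_mean_c,corr_sd_c
RV 1,RV,30.2,0.3,32.0,0.1,29.7,0.1
RV 2,RV,29.2,0.2,33.8,0.0,31.7,0.1
RV 3,RV,27.7,0.3,33.8,0.2,31.6,0.2
RV 4,RV,29.3,0.3,32.7,0.4,30.5,0.4
RV 5,RV,29.2,0.3,31.4,0.1,29.1,0.2
IV 1,IV,27.4,0.1,28.3,0.0,25.8,0.0
IV 2,IV,26.8,0.3,28.2,0.3,25.6,0.3
IV 3,IV,28.6,0.2,27.2,0.0,24.6,0.0
IV 4,IV,27.4,0.2,28.1,0.5,25.5,0.5
IV 5,IV,26.0,0.2,28.5,0.3,26.0,0.3
7d-IV 1,7d-IV,28.2,0.3,33.4,0.0,31.4,0.0
7d-IV 2,7d-IV,26.7,0.3,32.7,0.3,30.6,0.3
7d-IV 3,7d-IV,28.3,0.1,32.5,0.2,30.4,0.2
7d-IV 4,7d-IV,27.1,0.1,31.4,0.1,29.3,0.1
7d-IV 5,7d-IV,28.3,0.1,30.9,0.0,28.8,0.0
Soil 1,Soil,42.8,0.2,42.2,0.1,40.7,0.1
Soil 2,Soil,42.3,0.3,41.6,0.1,40.1,0.1
Soil 3,Soil,41.7,0.3,40.6,0.1,39.0,0.1
Soil 4,Soil,43.2,0.5,40.1,0.1,38.4,0.1
Soil 5,Soil,41.3,0.2,39.2,0.0,37.5,0.0
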