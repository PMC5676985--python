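gcp_id,error_x_m,error_y_m,error_z_m,image_residual_px
1,-0.37,0.46,-0.98,0.57
2,-0.19,-0.24,-0.04,1.65
3,0.02,0.32,0.13,0.64
4,0.05,-0.64,1.33,0.87
5,1.32,0.61,1.00,0.38
7,-0.98,-0.32,-1.78,0.67
8,-0.20,0.28,0.90,0.78
9,0.08,-0.39,-0.17,0.51
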