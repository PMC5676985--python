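gcp_id,error_x_m,error_y_m,error_z_m,image_residual_px
1,1.00,-1.12,0.80,0.58
2,-3.81,-0.33,2.78,0.97
3,4.82,1.65,-10.87,0.74
4,2.69,1.41,5.83,0.65
5,0.53,3.56,2.36,0.36
7,-2.41,-5.36,-6.14,0.56
8,-1.60,0.68,4.89,0.86
9,-1.48,0.33,-8.92,0.53
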