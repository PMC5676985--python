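pipeline,n_images,flight_height_m,ground_resolution_cm,covered_area_km2,images_oriented,tie_points,projections,reprojection_error_px
unfiltered,1154,81.1,13.8,0.366,1148,58193,272078,0.504
filtered,1154,80.4,13.5,0.364,1151,110089,445291,0.442
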