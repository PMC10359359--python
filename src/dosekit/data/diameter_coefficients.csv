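region,age_group,diameter_bin,manufacturer,median_k,q25_k,q75_k,n
chest,,11-15,,0.171,0.132,0.297,
chest,,16-20,,0.106,0.076,0.146,
chest,,21-25,,0.052,0.043,0.070,
chest,,26-30,,0.040,0.027,0.047,
chest,,31-35,,0.032,0.022,0.039,
cardiac,,11-15,,0.338,0.291,0.373,
cardiac,,16-20,,0.165,0.100,0.238,
cardiac,,21-25,,0.086,0.070,0.143,
cardiac,,26-30,,0.061,0.053,0.072,
abdomen_pelvis,,11-15,,0.087,0.058,0.124,
abdomen_pelvis,,16-20,,0.053,0.040,0.074,
abdomen_pelvis,,21-25,,0.029,0.021,0.035,
abdomen_pelvis,,26-30,,0.023,0.017,0.028,
abdomen_pelvis,,31-35,,0.018,0.014,0.023,
abdomen_pelvis,,36-40,,0.017,0.012,0.020,
chest_abdomen_pelvis,,11-15,,0.085,0.051,0.130,
chest_abdomen_pelvis,,16-20,,0.063,0.044,0.080,
chest_abdomen_pelvis,,21-25,,0.035,0.029,0.043,
chest_abdomen_pelvis,,26-30,,0.026,0.023,0.031,
chest_abdomen_pelvis,,31-35,,0.021,0.018,0.025,
chest_abdomen_pelvis,,36-40,,0.020,0.019,0.022,
spine,,16-20,,0.028,0.020,0.040,
spine,,21-25,,0.024,0.019,0.031,
spine,,26-30,,0.025,0.020,0.032,
spine,,31-35,,0.021,0.017,0.029,
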