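region,age_group,diameter_bin,manufacturer,median_k,q25_k,q75_k,n
head,<1,,,0.039,0.026,0.045,5507
head,1-4,,,0.013,0.009,0.018,12428
head,5-9,,,0.007,0.005,0.010,13630
head,10-14,,,0.004,0.003,0.006,17779
head,15-21,,,0.003,0.003,0.004,19487
neck,<1,,,0.165,0.105,0.273,158
neck,1-4,,,0.143,0.096,0.219,1364
neck,5-9,,,0.080,0.061,0.141,1976
neck,10-14,,,0.034,0.024,0.056,3202
neck,15-21,,,0.024,0.017,0.031,4431
chest,<1,,,0.285,0.163,0.344,864
chest,1-4,,,0.153,0.122,0.232,1746
chest,5-9,,,0.106,0.080,0.144,1919
chest,10-14,,,0.056,0.043,0.074,2773
chest,15-21,,,0.042,0.030,0.052,3951
cardiac,<1,,,0.372,0.345,0.391,256
cardiac,1-4,,,0.302,0.266,0.345,120
cardiac,5-9,,,0.217,0.190,0.278,49
cardiac,10-14,,,0.097,0.073,0.175,52
cardiac,15-21,,,0.094,0.058,0.135,47
abdomen_pelvis,<1,,,0.084,0.063,0.119,345
abdomen_pelvis,1-4,,,0.086,0.060,0.115,2241
abdomen_pelvis,5-9,,,0.054,0.042,0.072,5440
abdomen_pelvis,10-14,,,0.030,0.022,0.039,8738
abdomen_pelvis,15-21,,,0.023,0.017,0.030,12748
chest_abdomen_pelvis,<1,,,0.153,0.110,0.231,80
chest_abdomen_pelvis,1-4,,,0.092,0.073,0.121,599
chest_abdomen_pelvis,5-9,,,0.068,0.051,0.083,743
chest_abdomen_pelvis,10-14,,,0.037,0.030,0.050,1041
chest_abdomen_pelvis,15-21,,,0.030,0.023,0.037,1766
spine,1-4,,,0.063,0.055,0.079,48
spine,5-9,,,0.048,0.035,0.065,213
spine,10-14,,,0.030,0.022,0.041,928
spine,15-21,,,0.023,0.018,0.030,1725
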