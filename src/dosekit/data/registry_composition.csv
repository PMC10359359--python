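region,total,female,male,age_lt1,age_1_4,age_5_9,age_10_14,age_15_21,GE,Siemens,Philips,Canon
head,68831,29540,39291,5507,12428,13630,17779,19487,27071,31038,3964,6758
neck,11131,4851,6280,158,1364,1976,3202,4431,3664,5935,608,924
chest,11253,5146,6107,864,1746,1919,2773,3951,4294,6411,169,379
cardiac,524,199,325,256,120,49,52,47,59,456,4,5
abdomen_pelvis,29512,15153,14359,345,2241,5440,8738,12748,10590,13913,1729,3280
chest_abdomen_pelvis,4229,1820,2409,80,599,743,1041,1766,2592,1498,56,83
spine,2917,1316,1601,3,48,213,928,1725,1170,1282,350,115
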