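species,n,c_min,c_max,c_mean,c_se,n_min,n_max,n_mean,n_se,dbh_min,dbh_max,cn_min,cn_max,cn_mean,cn_se
Terminalia macroptera,19,46.267,51.241,49.474,0.266,0.108,0.303,0.192,0.013,9.3,40.7,160.50,428.39,281.81,18.33
Terminalia avicennioides,3,47.971,49.759,48.70,0.53,0.155,0.181,0.168,0.007,16.6,24,265.03,312.16,289.96,13.67
Acacia seyal,14,43.928,53.071,46.50,0.684,0.13,0.583,0.290,0.037,7.6,34.4,80.71,357.6,194.24,21.72
Acacia gourmaensis,2,47.55,48.09,47.824,0.269,0.297,0.349,0.323,0.025,13.4,19,137.80,160.11,148.95,11.15
Combretum glutinosum,11,41.737,45.959,44.72,0.438,0.14,0.358,0.241,0.020,8,32,125.94,320.95,201.36,19.15
Pterocarpus erinaceus,21,46.779,51.645,49.438,0.278,0.164,0.427,0.242,0.014,6.9,44.7,110.09,295.09,216.28,10.63
Anogeisus leiocarpus,16,44.037,46.003,44.917,0.167,0.08,0.273,0.128,0.012,6.9,32.4,161.30,570.05,386.52,28.28
Mitragyna inermis,18,44.978,47.74,46.724,0.174,0.177,0.354,0.243,0.011,7,34.5,129.46,262.19,199.40,9.23
Lannea microcrapa,20,42.091,45.938,44.282,0.209,0.148,0.405,0.273,0.015,7,50.3,110.95,306.08,173.47,11.14
Lannea acida,6,43.408,45.164,44.526,0.248,0.14,0.386,0.265,0.035,10.8,36,115.60,320.80,186.92,30.61
Ficus sp,21,43.931,46.38,45.153,0.139,0.16,0.427,0.294,0.015,8.6,52.7,105.3,286.90,163.14,9.83
Crosopteryx febrifuga,18,47.662,52.229,49.172,0.217,0.118,0.306,0.182,0.014,5.6,30.6,161.14,417.54,295.68,20.50
Entada Africana,15,45.852,48.377,47.098,0.191,0.242,0.475,0.357,0.016,8.4,27.6,100.09,196.18,135.97,6.75
Parkia biglobosa,23,44.02,47.636,46.516,0.214,0.127,0.396,0.201,0.013,8.6,62.4,119.40,358.43,247.85,12.35
Vitelaria paradoxa,22,45.972,50.032,47.942,0.228,0.13,0.337,0.228,0.010,8,60,136.41,367.23,220.11,11.37
Azadirachta indica,16,47.253,52.999,49.005,0.413,0.104,0.302,0.177,0.014,8.8,50.5,162.43,474.64,302.38,22.53
Anacardium occidentale,25,44.928,47.693,46.446,0.138,0.103,0.32,0.161,0.011,9.2,57.9,146,441.34,375.79,17.58
Eucalyptus grandis,7,47.018,49.031,47.744,0.350,0.125,0.191,0.157,0.011,5.7,29.2,247.25,376.14,310.57,21.94
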