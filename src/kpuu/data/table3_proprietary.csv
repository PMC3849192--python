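compound,invitro_1h,invitro_ss,invivo_slice
AZ10000568,0.03,0.14,0.03
AZ10003646,0.05,0.18,0.11
AZ10120857,0.06,0.74,1.00
AZ10129833,0.11,0.30,0.33
AZ10147710,0.04,0.03,0.03
AZ10281675,0.09,0.71,1.00
AZ10477650,0.07,0.04,0.01
AZ10582441,0.21,0.39,0.19
AZ10901745,0.22,0.46,0.80
AZ11125399,0.31,0.32,0.35
AZ11550918,0.19,0.24,0.34
AZ11931128,0.03,0.14,0.06
AZ12048147,0.05,0.11,0.09
AZ12065031,0.02,0.07,0.01
AZ12136053,0.12,0.04,0.12
AZ12558486,0.19,0.32,0.33
AZ12646603,0.19,0.45,0.29
AZ12659876,0.16,0.16,0.20
AZ12714134,0.20,0.69,0.40
AZ12806957,0.18,0.31,0.52
AZ12810256,0.14,0.31,0.30
AZ12917442,0.15,0.39,0.30
AZ12934216,0.19,0.30,0.22
AZ12995239,0.19,0.24,0.70
AZ13032000,0.17,0.15,0.19
AZ13121375,0.17,0.22,0.30
AZ13153303,0.11,0.49,0.60
AZ13189600,0.08,0.66,0.36
AZ13211419,0.05,0.54,0.85
AZ13219970,0.09,0.36,0.60
AZ13232626,0.10,0.52,0.40
AZ13234637,0.04,0.43,0.80
AZ13242018,0.09,0.55,0.50
AZ13242053,0.04,0.52,0.66
AZ13246373,0.12,0.42,0.29
AZ13246373,0.11,0.23,0.19
AZ13250995,0.04,0.56,0.59
AZ13252924,0.12,0.45,0.93
AZ13258888,0.24,0.48,0.55
AZ13263076,0.01,0.10,0.05
AZ13294800,0.04,0.42,1.00
AZ13308185,0.04,0.13,0.14
AZ13312621,0.13,0.15,0.20
AZ13314783,0.04,0.09,0.06
AZ13317127,0.29,0.57,1.00
AZ13320646,0.05,0.47,1.00
AZ13328768,0.02,0.03,0.06
AZ13335004,0.05,0.21,0.13
AZ13342097,0.26,0.29,1.00
AZ13366577,0.08,0.23,0.15
AZ13366866,0.24,0.67,0.62
AZ13382473,0.08,0.11,0.20
AZ13384126,0.08,0.66,1.00
AZ13395636,0.08,0.48,0.30
AZ13403802,0.13,0.10,0.20
AZ13410401,0.12,0.53,0.40
AZ13411057,0.15,0.11,0.16
AZ13415061,0.08,0.44,0.50
AZ13428599,0.05,0.08,0.14
AZ13445894,0.49,0.58,0.90
AZ13447772,0.27,0.69,1.00
AZ13451502,0.38,0.67,1.00
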