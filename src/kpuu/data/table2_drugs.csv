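compound,class,fu_homog_mean,fu_homog_sd,fu_slice_mean,fu_slice_sd,invitro_1h,invitro_ss,invivo_homog,invivo_slice
Amitriptyline,Base,0.0090,0.0005,0.0060,0.0003,0.07,0.59,1.10,0.73
Baclofen,Acid,0.5000,0.1000,0.5800,0.1610,0.05,0.06,0.02,0.02
Buproprion,Base,0.1710,0.0440,0.1600,0.0331,0.24,0.51,1.07,1.00
Caffeine,Neutral,0.5000,0.1180,0.7100,0.0780,0.34,0.55,0.48,0.68
Carbamazepine,Neutral,0.1160,0.0250,0.2000,0.0650,0.25,0.31,0.27,0.47
Carisoprodol,Neutral,0.2020,0.1200,0.5600,0.1600,0.31,0.61,0.34,0.95
Cetirizine,Base,0.0720,0.0210,0.1200,0.0510,0.03,0.01,0.01,0.01
Chlorpromazine,Base,0.0008,0.0001,0.0032,0.0005,0.06,0.69,0.12,0.49
Clozapine,Base,0.0094,0.0003,0.0100,0.0004,0.10,0.71,1.03,1.10
Diazepam,Neutral,0.0500,0.0120,0.0500,0.0215,0.16,0.32,0.49,0.49
Diphenhydramine,Base,0.0580,0.0170,0.0440,0.0130,0.13,0.55,1.38,1.05
Fexofenadine,Base,0.0770,0.0060,0.0048,0.0020,0.04,0.11,0.59,0.04
Fluoxetine,Base,0.0023,0.0001,0.0027,0.0002,0.10,0.96,0.85,1.00
Gabapentin,Base,0.7820,0.1400,0.2400,0.0430,0.06,0.14,0.46,0.14
Haloperidol,Base,0.0071,0.0003,0.0140,0.0009,0.09,0.70,0.56,1.10
Hydroxyzine,Base,0.0100,0.0060,0.0170,0.0093,0.05,0.47,0.51,0.86
Indinavir,Base,0.1000,0.0380,0.1900,0.0480,0.04,0.10,0.07,0.14
Lamotrigine,Neutral,0.2000,0.0270,0.3600,0.0350,0.27,0.43,0.34,0.61
Morphine,Base,0.5000,0.0410,0.3700,0.0370,0.14,0.31,0.20,0.15
Nortriptyline,Base,0.0046,0.0004,0.0045,0.0007,0.08,0.81,1.02,1.00
Paroxetin,Base,0.0039,0.0003,0.0024,0.0004,0.08,0.79,0.86,0.53
Phenytoin,Acid,0.0800,0.0130,0.1200,0.0070,0.22,0.44,0.28,0.42
Risperidone,Base,0.0700,0.0190,0.0700,0.0207,0.56,0.60,0.27,0.27
Sertraline,Base,0.0007,0.0004,0.0023,0.0003,0.04,0.76,0.29,1.00
Sulpiride,Base,0.6000,0.1700,0.4400,0.0270,0.05,0.09,0.07,0.05
Sumatriptan,Base,0.4000,0.0960,0.6100,0.1510,0.05,0.05,0.05,0.07
Tacrine,Base,0.1200,0.0210,0.1200,0.0330,0.23,0.58,0.78,0.78
Thioridazine,Base,0.0010,0.0002,0.0017,0.0001,0.08,0.68,0.26,0.45
Trifluoperazine,Base,0.0007,0.0001,0.0007,0.0001,0.09,0.71,1.00,1.00
Zolpidem,Base,0.2000,0.0340,0.3500,0.0456,0.25,0.49,0.24,0.42
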