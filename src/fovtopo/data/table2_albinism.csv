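participant,race,age_years,sex,al_od_mm,al_os_mm,bcva_od_logmar,bcva_os_logmar
JC_0131,Unknown,20,M,24.94,24.87,0.28,0.28
JC_0456,Black,19,M,23.62,22.92,0.34,0.54
JC_0492,White,27,F,23.53,23.48,0.14,0.16
JC_0493,White,20,F,22.33,22.23,0.30,0.00
JC_10093,White,22,M,21.40,22.19,0.66,0.56
JC_10193,White,16,M,24.99,25.30,0.24,0.26
JC_10278,White,14,M,22.82,22.42,0.18,0.46
JC_10508,White,37,F,22.18,,0.16,0.28
JC_10725,Unknown,21,F,22.14,22.15,0.60,0.58
JC_10726,Unknown,22,M,23.44,21.96,0.82,0.70
JC_10797,Other,15,M,22.65,22.44,0.46,0.46
BB_10965,White,44,F,23.91,24.99,0.26,0.24
GS_10979,White,17,M,24.10,24.04,0.08,0.26
JC_11046,White,37,M,26.02,25.33,0.54,0.66
GS_11148,White,9,F,21.31,20.88,0.24,0.60
JC_11430,White,16,F,23.40,22.15,0.28,0.32
GS_11807,White,37,M,23.78,24.05,0.70,0.68
JC_11822,White,40,F,21.51,21.55,0.74,0.84
JC_11824,White,12,F,23.22,23.15,0.52,0.54
AD_11837,White,16,M,24.56,24.05,0.16,0.06
JC_11849,White,25,F,22.48,22.34,0.70,0.54
JC_11850,White,33,M,20.15,19.99,0.78,0.88
JC_11851,White,37,F,22.25,21.73,0.72,0.76
JC_11854,Black,33,F,26.97,26.81,0.64,0.56
AD_11897,Black,49,M,21.64,21.71,0.72,0.64
JC_11899,White,13,F,27.37,27.03,0.72,0.58
AD_11925,Unknown,22,M,22.03,22.04,0.58,0.58
JC_11934,White,10,M,23.12,22.91,1.00,1.00
SS_11938,White,22,F,22.40,22.14,0.14,0.22
AD_11941,White,11,M,23.99,24.10,0.32,0.34
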