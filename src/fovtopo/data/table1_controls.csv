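participant,race,age_years,sex,al_od_mm,al_os_mm
JC_0077,White,14,F,24.15,24.11
JC_0200,White,30,M,24.47,24.66
JC_0878,White,12,F,24.03,23.99
JC_0905,White,25,M,22.78,21.98
JC_10312,White,18,M,27.06,26.98
JC_10339,White,29,F,23.54,23.76
JC_10549,White,25,M,24.00,23.89
JC_10567,White,27,F,22.32,22.47
JC_10591,White,26,M,23.56,23.57
JC_11144,Asian,24,M,25.46,25.35
JC_11295,Asian,29,M,22.90,22.94
JC_11314,Black,23,F,24.11,23.84
JC_11321,Asian,29,F,23.71,23.61
JC_11335,White,33,F,24.02,23.86
JC_11341,White,27,F,22.98,23.04
JC_11344,Asian,27,M,24.66,24.78
JC_11350,Black,33,M,23.12,23.20
JC_11354,Native Hawaiian/Pacific Islander,24,F,24.53,24.50
JC_11357,Black,23,M,24.25,24.49
JC_11360,Asian,28,F,23.57,23.58
JC_11364,White,32,F,25.86,25.95
JC_11367,Black,22,M,25.33,25.34
JC_11412,White,23,M,25.32,25.35
JC_11442,White,24,M,23.70,23.63
JC_11617,White,48,F,24.06,23.77
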