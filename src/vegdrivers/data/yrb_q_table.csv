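factor,1980,1990,2000,2010,2019
MT,0.30,0.29,0.32,0.30,0.33
MP,0.66,0.72,0.72,0.79,0.72
MD,0.25,0.25,0.26,0.261,0.16
MS,0.54,0.51,0.56,0.6,0.57
PD,0.23,0.23,0.07,0.06,0.17
EPR,0.15,0.06,0.115,0.07,0.093
PI,0.08,0.2,0.034,0.13,0.003
FR,0.09,0.06,0.048,0.03,0.175
GY,0.23,0.16,0.28,0.09,0.234
PG,0.08,0.048,0.16,0.11,0.16
PC,0.11,0.16,0.06,0.06,0.027
IR,0.09,0.12,0.11,0.18,0.049
IS,0.1,0.16,0.022,0.04,0.02
IOR,0.087,0.18,0.068,0.06,0.23
GRGR,,,,0.245,0.31
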