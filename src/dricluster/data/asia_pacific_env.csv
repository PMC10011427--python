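country,AQ,WS,HM,WM
TLS,0.12,0.15,0.12,0.13
JPN,0.45,0.54,0.49,0.40
PHL,0.17,0.31,0.30,0.24
SOL,0.28,0.15,0.12,0.16
SKR,0.17,0.25,0.13,0.09
PNG,0.26,0.26,0.21,0.11
KHM,0.85,0.98,0.79,1.00
TWN,0.27,0.03,0.15,0.16
VNM,0.03,0.21,0.17,0.00
VUT,0.21,0.00,0.00,0.05
THA,0.10,0.18,0.12,0.33
MIC,0.31,0.22,0.28,0.48
CHN,0.75,0.95,0.85,1.00
MNG,0.18,0.48,0.29,0.27
IDN,0.49,0.72,0.64,0.80
FIJ,0.73,0.88,0.57,0.81
WSM,0.25,0.09,0.27,0.44
BRN,1.00,1.00,1.00,0.70
LAO,0.33,0.43,0.57,0.67
TON,0.00,0.36,0.10,0.12
KIR,0.42,0.40,0.71,0.37
SGP,0.26,0.02,0.46,0.28
MHL,0.24,0.25,0.68,0.40
MYS,0.30,0.52,0.74,0.32
MMR,0.09,0.56,0.16,0.32
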