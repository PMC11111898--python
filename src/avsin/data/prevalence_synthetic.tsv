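# SYNTHETIC placeholder phoneme-prevalence table (relative frequencies of the
# 39 ARPAbet phonemes in spoken American English). These values are plausible
# round numbers authored for testing the prevalence-weighting machinery only;
# substitute a published frequency table for real corpus extrapolation.
# columns: phoneme <tab> relative_frequency
AH	0.085
N	0.070
T	0.068
IH	0.060
S	0.048
R	0.047
D	0.042
L	0.040
IY	0.037
DH	0.035
K	0.033
EH	0.031
M	0.030
Z	0.029
ER	0.028
AE	0.026
W	0.024
HH	0.023
P	0.022
B	0.021
AY	0.020
F	0.019
OW	0.018
V	0.018
EY	0.017
AA	0.016
UW	0.015
G	0.013
AO	0.012
Y	0.011
NG	0.010
SH	0.009
TH	0.007
JH	0.005
CH	0.005
AW	0.004
UH	0.004
OY	0.001
ZH	0.001
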