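phoneme	viseme_class
P	bilabial
B	bilabial
M	bilabial
F	labiodental
V	labiodental
TH	dental
DH	dental
T	alveolar
D	alveolar
S	alveolar
Z	alveolar
N	alveolar
L	alveolar
SH	postalveolar
ZH	postalveolar
CH	postalveolar
JH	postalveolar
K	velar
G	velar
NG	velar
HH	velar
W	rounded
R	rounded
UW	rounded
UH	rounded
OW	rounded
AO	rounded
OY	rounded
AW	rounded
IY	spread
IH	spread
EY	spread
EH	spread
AE	spread
AY	spread
Y	spread
AA	open
AH	open
ER	open
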