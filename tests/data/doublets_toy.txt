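GG
GS
SG
AG
WG
RG
LG
NG
QG
YG
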