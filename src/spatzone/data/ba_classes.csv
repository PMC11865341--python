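analyte,ba_class
CA,12-OH
DCA,12-OH
TCA,12-OH
GCA,12-OH
TDCA,12-OH
GDCA,12-OH
CDCA,non-12-OH
LCA,non-12-OH
UDCA,non-12-OH
HDCA,non-12-OH
HCA,non-12-OH
a-MCA,non-12-OH
b-MCA,non-12-OH
w-MCA,non-12-OH
Iso-LCA,non-12-OH
7-KetoLCA,non-12-OH
TCDCA,non-12-OH
TLCA,non-12-OH
TUDCA,non-12-OH
THDCA,non-12-OH
THCA,non-12-OH
T-a-MCA,non-12-OH
T-b-MCA,non-12-OH
T-w-MCA,non-12-OH
GCDCA,non-12-OH
GLCA,non-12-OH
GUDCA,non-12-OH
GHDCA,non-12-OH
GHCA,non-12-OH
G-b-MCA,non-12-OH
UCA,unclassified
APCA,unclassified
NorCA,unclassified
NorDCA,unclassified
3-oxoCA,unclassified
Dio-LCA,unclassified
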