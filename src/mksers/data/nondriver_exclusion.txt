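# Default non-driver exclusion list for top-mutated-gene ranking.
# Recurrently mutated large/passenger genes; override with your own file.
TTN
MUC16
MUC4
OBSCN
AHNAK
AHNAK2
SYNE1
SYNE2
FLG
CSMD1
CSMD3
RYR2
RYR3
USH2A
DNAH5
DNAH11
PCLO
HMCN1
DST
ADGRV1
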