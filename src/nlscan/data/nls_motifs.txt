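# Curated NLS-like motifs (PROSITE-flavoured dialect).
# Monopartite K/R-rich motifs
PRRRK
RKRKK
RPRRK
KRPRP
RKRRR
KAKRQR
QRKRQK
RRKGKEK
KRKRRP
GKKRSKA
IKYFKKFPKD
# Motifs with wildcard spacers
P.KKKRK
TKRS…M
KR.{10}KKKL
# Bipartite motifs: two basic clusters separated by a long spacer
K[RK]{3,5}.{11,18}[RK]K.{2,3}K
[KR]{4}.{20,24}K{1,4}.K
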