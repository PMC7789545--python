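# HUGO gene symbols recognized by the mention recognizer (one per line).
# Extend or replace via --gene-dict; the full HUGO list is a pluggable input.
BRCA1
BRCA2
EGFR
TP53
ATM
PALB2
CHEK2
PTEN
RAD51
RAD51C
RAD51D
BARD1
BRIP1
CDH1
STK11
MLH1
MSH2
MSH6
PMS2
NBN
ERBB2
KRAS
PIK3CA
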