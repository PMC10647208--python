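# Commonly used amplicon-survey primers, keyed by name.
# 16S V4-V5 (bacteria)
515FB: GTGYCAGCMGCCGCGGTAA
926R: CCGYCAATTYMTTTRAGTTT
# ITS1 (fungi)
BITS: ACCTGCGGARGGATCA
B58S3: GAGATCCRTTGYTRAAAGTT
# Fusarium translation elongation factor 1-alpha
Fa-150: CCGGTCACTTGATCTACCAG
Ra-2: ATGACGGTGACATAGTAGCG
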