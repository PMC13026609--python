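"""GRCh38 autosome lengths used to lay out synthetic panel fixtures."""

import numpy as np

# chr1..chr22 sequence lengths in base pairs (GRCh38 primary assembly).
GRCH38_AUTOSOME_BP = np.array(
    [
        248_956_422,
        242_193_529,
        198_295_559,
        190_214_555,
        181_538_259,
        170_805_979,
        159_345_973,
        145_138_636,
        138_394_717,
        133_797_422,
        135_086_622,
        133_275_309,
        114_364_328,
        107_043_718,
        101_991_189,
        90_338_345,
        83_257_441,
        80_373_285,
        58_617_616,
        64_444_167,
        46_709_983,
        50_818_468,
    ],
    dtype=np.int64,
)

TOTAL_AUTOSOME_MBP = float(GRCH38_AUTOSOME_BP.sum() / 1e6)  # ~2875 Mbp

# Sex-averaged autosomal genetic length of the human genome (deCODE-style
# pedigree maps: ~2,600 cM male, ~4,400 cM female).  The default uniform map
# is scaled to this total so that recombination counts per meiosis are
# realistic even though the map's shape is flat.
TOTAL_AUTOSOME_CM = 3500.0

AVG_CM_PER_MBP = TOTAL_AUTOSOME_CM / TOTAL_AUTOSOME_MBP  # ~1.217
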