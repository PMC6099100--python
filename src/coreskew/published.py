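"""Published genome-survey numbers for the L. acidophilus complex.

Replichore x strand gene counts and mRNA-mass headline figures reported
for the six reference genomes of the clade (L. acidophilus NCFM,
L. amylovorus GRL 1112, L. delbrueckii subsp. bulgaricus ATCC 11842,
L. crispatus ST1, L. gasseri ATCC 33323, L. helveticus CNRZ32).  These
are inputs for arithmetic cross-checks of the strand-bias reporter —
the per-class counts are published values, and the forward/reverse
totals and percentages are recomputed from them by this package.
"""

from __future__ import annotations

#: organism -> replichore x strand class counts (coding genes)
STRAND_CLASS_COUNTS: dict[str, dict[str, int]] = {
    "Lac": {"right_fwd": 821, "right_rev": 230, "left_rev": 183, "left_fwd": 600},
    "Lam": {"right_fwd": 766, "right_rev": 247, "left_rev": 185, "left_fwd": 498},
    "Lbu": {"right_fwd": 632, "right_rev": 151, "left_rev": 185, "left_fwd": 581},
    "Lcr": {"right_fwd": 849, "right_rev": 254, "left_rev": 193, "left_fwd": 643},
    "Lga": {"right_fwd": 788, "right_rev": 174, "left_rev": 224, "left_fwd": 586},
    "Lhe": {"right_fwd": 766, "right_rev": 234, "left_rev": 136, "left_fwd": 568},
}

#: smallest published 50%-mRNA-mass set and its genome's coding-gene total
#: (L. bulgaricus had the largest such set: 57 genes of 1,549)
BULGARICUS_HALF_MASS_GENES = 57
BULGARICUS_CODING_GENES = 1549
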