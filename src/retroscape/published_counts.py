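"""Published genus-wide citrus LTR-retrotransposon survey counts.

Reference tallies from the published eight-genome citrus survey, used as
inputs for ratio arithmetic and bookkeeping checks: per-genome core counts,
complete-element counts, and the paired/solo/nonsolo LTR class counts for
the Clementine reference and for the eight genomes combined.
"""

from __future__ import annotations

from .ltrscape import LTRClassCounts

GENOMES = (
    "C.cle", "C.sin", "C.uns", "C.max", "C.med", "C.ich", "C.ret", "S.bux",
)

#: total validated retrotransposon cores per genome
CORE_COUNTS = {
    "C.cle": 4_605,
    "C.sin": 3_145,
    "C.uns": 3_595,
    "C.max": 5_448,
    "C.med": 4_942,
    "C.ich": 4_040,
    "C.ret": 3_941,
    "S.bux": 2_790,
}

#: complete (two-LTR) elements per genome
COMPLETE_ELEMENT_COUNTS = {
    "C.cle": 3_102,
    "C.sin": 1_531,
    "C.uns": 1_777,
    "C.max": 3_410,
    "C.med": 2_863,
    "C.ich": 2_357,
    "C.ret": 2_129,
    "S.bux": 1_461,
}

#: LTR class counts for the Clementine reference genome
CLEMENTINE_CLASS_COUNTS = LTRClassCounts(paired=9_826, solo=15_471, nonsolo=5_924, discarded=4)

#: LTR class counts pooled over the eight genomes
GENUS_CLASS_COUNTS = LTRClassCounts(paired=96_381, solo=123_743, nonsolo=54_009, discarded=22)
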