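"""Assay identifiers and locus bookkeeping for the RCCX copy number variation.

The RCCX module is a tandem copy-number variation on chromosome 6p21.3.
Each repeated segment carries one complement C4 gene (either *C4A* or
*C4B*, optionally interrupted by the HERV-K(C4) retroviral insertion in
intron 9) and one steroid 21-hydroxylase gene (the active *CYP21A2* or
the *CYP21A1P* pseudogene).  Seven duplex qPCR assays interrogate the
module: one per paralogous allele of the three bi-allelic elements plus
one for the junction ("breakpoint") between adjacent segments.  Every
assay co-amplifies the single-copy *RPPH1* reference gene.
"""

from __future__ import annotations

# Canonical assay identifiers, in reporting order.
ASSAYS: tuple[str, ...] = (
    "C4A",
    "C4B",
    "CYP21A1P",
    "CYP21A2",
    "HERV_del",
    "HERV_ins",
    "BP",
)

#: Paralogous pairs whose copy numbers sum to the segment total.
PARALOG_PAIRS: tuple[tuple[str, str], ...] = (
    ("C4A", "C4B"),
    ("CYP21A1P", "CYP21A2"),
    ("HERV_del", "HERV_ins"),
)

#: Default duplex reference gene (present exactly once per haploid genome).
REFERENCE_GENE = "RPPH1"

CHANNELS = ("target", "reference")

STUDY_GROUPS = ("good", "population", "bad")


def locus_counts_to_totals(counts: dict[str, int | float]) -> list[float]:
    """Four independent estimates of the total segment count.

    ``counts`` maps assay id to a (measured or integer) copy number.  The
    genomic structure forces C4A+C4B = CYP21A1P+CYP21A2 =
    HERV_del+HERV_ins = breakpoints+2 = number of segments; the four sums
    are returned in that order.
    """
    return [
        counts["C4A"] + counts["C4B"],
        counts["CYP21A1P"] + counts["CYP21A2"],
        counts["HERV_del"] + counts["HERV_ins"],
        counts["BP"] + 2,
    ]
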