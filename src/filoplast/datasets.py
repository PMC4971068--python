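"""Bundled example dataset.

Per-segment assembly lengths and directed pairwise variant counts for a
six-segment survey of a single clonal filament of a giant, highly polyploid
sulfur bacterium (~3.2 Mbp genome, ~88% coding; segments 5 and 6 assembled
less completely and show inflated divergence).  Only counts and lengths are
stored; every per-100-kbp rate and every mean +/- sd summary is recomputed
by the package, which makes the dataset a compact end-to-end check of the
rate arithmetic and a ready-made worked example.
"""

from __future__ import annotations

from .pairdiff import PairwiseComparison, comparison_from_counts

#: segment id -> (assembly bp, CDS bp, nCDS bp); CDS + nCDS == assembly
SEGMENT_LENGTHS: dict[int, tuple[int, int, int]] = {
    1: (3_210_343, 2_836_815, 373_528),
    2: (3_217_969, 2_843_091, 374_878),
    3: (3_239_714, 2_882_289, 357_425),
    4: (3_116_424, 2_757_582, 358_842),
    5: (2_544_604, 2_221_023, 323_581),
    6: (2_402_354, 2_106_546, 295_808),
}

#: (reference, query) -> (total SNPs, total indels, SNPs in CDS, indels in CDS)
PAIR_COUNTS: dict[tuple[int, int], tuple[int, int, int, int]] = {
    (1, 2): (132, 8, 91, 3),
    (1, 3): (86, 14, 66, 0),
    (1, 4): (145, 27, 124, 8),
    (1, 5): (300, 41, 136, 12),
    (1, 6): (757, 82, 316, 15),
    (2, 1): (151, 16, 94, 3),
    (2, 3): (132, 15, 116, 3),
    (2, 4): (135, 17, 135, 3),
    (2, 5): (302, 44, 138, 12),
    (2, 6): (682, 64, 303, 13),
    (3, 1): (84, 24, 84, 0),
    (3, 2): (118, 15, 101, 3),
    (3, 4): (194, 24, 118, 8),
    (3, 5): (341, 47, 140, 12),
    (3, 6): (798, 76, 325, 15),
    (4, 1): (126, 24, 91, 8),
    (4, 2): (153, 13, 94, 3),
    (4, 3): (146, 24, 112, 8),
    (4, 5): (358, 43, 158, 21),
    (4, 6): (568, 64, 301, 13),
    (5, 1): (374, 55, 192, 17),
    (5, 2): (352, 54, 162, 17),
    (5, 3): (394, 61, 153, 17),
    (5, 4): (456, 59, 209, 26),
    (5, 6): (548, 58, 201, 16),
    (6, 1): (663, 80, 354, 15),
    (6, 2): (624, 75, 339, 13),
    (6, 3): (712, 76, 342, 15),
    (6, 4): (649, 77, 345, 15),
    (6, 5): (587, 65, 193, 16),
}

SEGMENTS: list[int] = sorted(SEGMENT_LENGTHS)


def example_survey_comparisons() -> list[PairwiseComparison]:
    """The example survey as directed :class:`PairwiseComparison` objects,
    with all rates recomputed from the stored counts and lengths."""
    out = []
    for (ref, qry), (snps, indels, snps_cds, indels_cds) in sorted(
            PAIR_COUNTS.items()):
        total, cds, ncds = SEGMENT_LENGTHS[qry]
        out.append(comparison_from_counts(
            ref, qry, total, cds, ncds, snps, indels, snps_cds, indels_cds))
    return out


def example_survey_matrix() -> dict:
    """Matrix blocks (one per reference segment) for the example survey."""
    from .report import build_matrix

    return build_matrix(example_survey_comparisons(), SEGMENTS)
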