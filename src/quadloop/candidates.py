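"""Curated long-loop PG4 candidates from human mRNA UTRs.

These 20 experimentally characterized candidates (10 long-loop-1, 10
long-loop-3) serve as worked examples for the scanner: each entry records the
published decomposition — four G-tracks of three guanines plus three loop
sequences — along with its UTR coordinates.  ``reconstruct`` rebuilds the
motif sequence by concatenation; re-scanning it with the matching pattern
must recover the published loop lengths and total length.

The DDX43 entry is flagged inconsistent: its published total length (29)
disagrees with the sum of its parts (25), so it is excluded from exact
reconstruction checks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .g4_scanner import BUILTIN_PATTERNS, PatternSpec
from .sequence_model import normalize_alphabet

G_TRACK = "GGG"


@dataclass(frozen=True)
class CandidateRow:
    gene: str
    accession: str
    region_kind: str  # utr5 | utr3
    utr_length: int
    utr_position: int  # signed 1-based position within the UTR
    length: int  # published total motif length
    loops: tuple[str, str, str]
    pattern_name: str  # PLL1 | PLL3
    long_loop_len: int  # published length of the oversized loop
    length_consistent: bool = True

    @property
    def pattern(self) -> PatternSpec:
        return BUILTIN_PATTERNS[self.pattern_name]

    def reconstruct(self) -> str:
        """Concatenate T1+L1+T2+L2+T3+L3+T4 as a normalized RNA string."""
        l1, l2, l3 = (normalize_alphabet(loop) for loop in self.loops)
        return G_TRACK + l1 + G_TRACK + l2 + G_TRACK + l3 + G_TRACK

    @property
    def loop_lengths(self) -> tuple[int, int, int]:
        return tuple(len(loop) for loop in self.loops)


LONG_LOOP1_CANDIDATES: tuple[CandidateRow, ...] = (
    CandidateRow("BNIP1", "NM_013978", "utr5", 104, 7, 30,
                 ("cgcugccccgagacu", "u", "ga"), "PLL1", 15),
    CandidateRow("DDX43", "NM_018665", "utr5", 344, 190, 29,
                 ("auagagagcgu", "c", "g"), "PLL1", 11,
                 length_consistent=False),
    CandidateRow("AVPR1B", "NM_000707", "utr3", 340, 61, 33,
                 ("cacuggaaaugagagcu", "a", "uaa"), "PLL1", 17),
    CandidateRow("B3GNT8", "NM_198540", "utr3", 226, 45, 55,
                 ("gccggccccuggcucagccccuccuuccaggucuugau", "a", "agga"),
                 "PLL1", 38),
    CandidateRow("CYSRT1", "NM_199001", "utr3", 255, 18, 65,
                 ("ccaggacccagacuucagcaaauguggcucacacagugcc", "acaugcc",
                  "acaugc"), "PLL1", 40),
    CandidateRow("DAG1", "NM_004393", "utr3", 2419, 1612, 54,
                 ("aggaaugccuuucgcaauaauguauccauucccugauuga", "u", "u"),
                 "PLL1", 40),
    CandidateRow("DUSP15", "NM_001012644", "utr3", 336, 189, 52,
                 ("ccggccugcugcagccaccuggugccuuaguccuu", "cu", "gga"),
                 "PLL1", 35),
    CandidateRow("KIF26A", "NM_15656", "utr3", 1101, 119, 40,
                 ("agucucagagaggagacggagugu", "gga", "a"), "PLL1", 24),
    CandidateRow("SPHK2", "NM_001243876", "utr3", 633, 477, 54,
                 ("gccggcgcuaggauuugcacuaauguuccucuccccgc", "u", "ggc"),
                 "PLL1", 38),
    CandidateRow("TADA3", "NM_006354", "utr3", 393, -6, 55,
                 ("UAGcccucaccccugccucaggcugauuaucuggccua", "ga", "gaa"),
                 "PLL1", 38),
)

LONG_LOOP3_CANDIDATES: tuple[CandidateRow, ...] = (
    CandidateRow("GRIA1", "NM_000827", "utr5", 365, 297, 41,
                 ("aaa", "g", "aaacaccaaaucuaugauuggaccu"), "PLL3", 25),
    CandidateRow("RNF111", "NM_001270530", "utr5", 279, 151, 61,
                 ("agugu", "ugag",
                  "auuucucucccacuuccgacucucccuagagucucaggau"), "PLL3", 40),
    CandidateRow("TEF", "NM_003216", "utr5", 116, 69, 43,
                 ("gggc", "c", "ggaggcgaggugcgcgagccgagucc"), "PLL3", 26),
    CandidateRow("DCTN5", "NM_032486", "utr3", 6603, 5366, 43,
                 ("a", "a", "aggaagcaagcaagugaacaaaugagucu"), "PLL3", 29),
    CandidateRow("DOK1", "NM_001197260", "utr3", 437, 91, 33,
                 ("u", "a", "gccaugcugugugagacca"), "PLL3", 19),
    CandidateRow("MTF1", "NM_005955", "utr3", 5569, 3473, 54,
                 ("u", "u", "uuuuccugagagacuuuguauaaugcugaauguguccaga"),
                 "PLL3", 40),
    CandidateRow("PLXNB1", "NM_001130082", "utr3", 632, 250, 58,
                 ("aguu", "gacuaa",
                  "cuuccagagaguggcuggaagagacuccaggccccu"), "PLL3", 36),
    CandidateRow("PTPRU", "NM_133178", "utr3", 1152, 965, 30,
                 ("u", "u", "aaggucucuuuaaaau"), "PLL3", 16),
    CandidateRow("STRIP2", "NM_020704", "utr3", 2569, 95, 42,
                 ("cucuucu", "ggcucuu", "ccuaaagauggugcaa"), "PLL3", 16),
    CandidateRow("TNRC6C", "NM_018996", "utr3", 3990, 3775, 54,
                 ("aacucg", "gacagga", "cagcacaguguaagcuaaagcccugugua"),
                 "PLL3", 29),
)

ALL_CANDIDATES: tuple[CandidateRow, ...] = (
    LONG_LOOP1_CANDIDATES + LONG_LOOP3_CANDIDATES
)

#: Entries whose published parts sum to the published total length.
CONSISTENT_CANDIDATES: tuple[CandidateRow, ...] = tuple(
    row for row in ALL_CANDIDATES if row.length_consistent
)


def get_candidate(gene: str) -> CandidateRow:
    for row in ALL_CANDIDATES:
        if row.gene == gene:
            return row
    raise KeyError(f"no candidate named {gene!r}")
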