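"""Scanner for potential G-quadruplex (PG4) motifs with oversized loops.

A motif is four G-tracks separated by three loops whose lengths are bounded
per pattern.  Matching is *lazy* (minimal): each reported track takes exactly
``min_track_len`` guanines — surplus guanines of a longer run belong to the
neighbouring loops or to the flanks — and each loop takes the fewest
nucleotides such that a complete match exists.  Ties break lexicographically
on (start, |L1|, |L2|, |L3|); among complete matches the leftmost start wins.
Successive matches never overlap: scanning resumes at the previous hit's end.

Lazy semantics matter: they carve loop 1 out of the front of an extended
G-run (e.g. a ``GGGGGGC...`` prefix parses as track ``GGG`` + loop ``GGGC``),
which greedy matching would not; fixed-length tracks keep a guanine that
trails a short loop inside that loop rather than growing the next track.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace

from .sequence_model import Region, TranscriptRecord, utr_position

logger = logging.getLogger(__name__)

MAX_LONG_LOOP = 40
MAX_SHORT_LOOP = 7
LONG_LOOP_MIN = 8  # loops of 8..40 nt count as "long"


@dataclass(frozen=True)
class PatternSpec:
    """A four-track / three-loop motif definition."""

    name: str
    loop_bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    min_track_len: int = 3

    def __post_init__(self) -> None:
        if self.min_track_len < 3:
            raise ValueError("min_track_len must be >= 3")
        for lo, hi in self.loop_bounds:
            if not (1 <= lo <= hi):
                raise ValueError(f"invalid loop bounds ({lo}, {hi})")

    def regex(self) -> re.Pattern[str]:
        g = f"(G{{{self.min_track_len}}})"
        parts = [g]
        for lo, hi in self.loop_bounds:
            parts.append(f"([ACGUN]{{{lo},{hi}}}?)")
            parts.append(g)
        return re.compile("".join(parts))


#: Long loop 1: Gx N1-40 Gx N1-7 Gx N1-7 Gx, x >= 3.
PLL1 = PatternSpec("PLL1", ((1, 40), (1, 7), (1, 7)))
#: Long loop 3: Gx N1-7 Gx N1-7 Gx N1-40 Gx, x >= 3.
PLL3 = PatternSpec("PLL3", ((1, 7), (1, 7), (1, 40)))
#: Classical motif with all loops 1-7 nt.
CANONICAL = PatternSpec("CANONICAL", ((1, 7), (1, 7), (1, 7)))

BUILTIN_PATTERNS = {p.name: p for p in (PLL1, PLL3, CANONICAL)}


@dataclass
class G4Hit:
    """A located PG4 match with its full track/loop decomposition.

    ``tracks`` and ``loops`` are half-open (start, end) spans in transcript
    coordinates, alternating T1 L1 T2 L2 T3 L3 T4 and tiling [start, end).
    """

    start: int
    end: int
    tracks: tuple[tuple[int, int], ...]
    loops: tuple[tuple[int, int], ...]
    sequence: str
    pattern_name: str
    loop_class: str = ""
    transcript_accession: str = ""
    gene: str = ""
    region_kind: str = ""
    utr_position: int | None = None
    multiplicity: int = 1
    cgcc_score: float | None = None

    @property
    def track_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.tracks)

    @property
    def loop_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.loops)

    def loop_seq(self, i: int) -> str:
        s, e = self.loops[i]
        return self.sequence[s - self.start : e - self.start]

    def track_seq(self, i: int) -> str:
        s, e = self.tracks[i]
        return self.sequence[s - self.start : e - self.start]

    @property
    def loop_offsets(self) -> frozenset[int]:
        """Hit-local 0-based offsets of loop nucleotides."""
        return frozenset(
            i for s, e in self.loops for i in range(s - self.start, e - self.start)
        )

    @property
    def track_offsets(self) -> frozenset[int]:
        return frozenset(
            i for s, e in self.tracks for i in range(s - self.start, e - self.start)
        )


def classify_hit(hit: G4Hit) -> str:
    """Classify by loop geometry: canonical, long_loop1, long_loop3, long_both."""
    l1, _, l3 = hit.loop_lengths
    if l1 > MAX_LONG_LOOP or l3 > MAX_LONG_LOOP:
        raise ValueError(f"loop length exceeds {MAX_LONG_LOOP} nt: {hit.loop_lengths}")
    long1 = l1 >= LONG_LOOP_MIN
    long3 = l3 >= LONG_LOOP_MIN
    if long1 and long3:
        warnings.warn("hit has both loop 1 and loop 3 long; labelling long_both")
        return "long_both"
    if long1:
        return "long_loop1"
    if long3:
        return "long_loop3"
    return "canonical"


def _hit_from_match(m: re.Match[str], pattern: PatternSpec) -> G4Hit:
    spans = [m.span(i) for i in range(1, 8)]
    tracks = tuple(spans[0::2])
    loops = tuple(spans[1::2])
    hit = G4Hit(
        start=m.start(),
        end=m.end(),
        tracks=tracks,
        loops=loops,
        sequence=m.group(0),
        pattern_name=pattern.name,
    )
    hit.loop_class = classify_hit(hit)
    return hit


def scan_sequence(seq: str, pattern: PatternSpec) -> list[G4Hit]:
    """Left-to-right non-overlapping lazy scan of a normalized RNA string."""
    rx = pattern.regex()
    hits: list[G4Hit] = []
    pos = 0
    while True:
        m = rx.search(seq, pos)
        if m is None:
            return hits
        hits.append(_hit_from_match(m, pattern))
        pos = m.end()


def scan_transcript(record: TranscriptRecord, pattern: PatternSpec) -> list[G4Hit]:
    """Scan a full transcript and keep hits lying mostly (>50%) in a UTR.

    The kept hit is annotated with its UTR kind and signed 1-based UTR
    position (negative when the hit starts upstream of the UTR).
    """
    kept: list[G4Hit] = []
    for hit in scan_sequence(record.sequence, pattern):
        n = hit.end - hit.start
        region = _majority_utr(record, hit.start, hit.end, n)
        if region is None:
            continue
        hit.transcript_accession = record.accession
        hit.gene = record.gene
        hit.region_kind = region.kind
        hit.utr_position = utr_position(region, hit.start)
        kept.append(hit)
    return kept


def _majority_utr(
    record: TranscriptRecord, start: int, end: int, n: int
) -> Region | None:
    best: Region | None = None
    best_ov = 0
    for region in (record.utr5, record.utr3):
        ov = min(end, region.end) - max(start, region.start)
        if ov > best_ov:
            best_ov = ov
            best = region
    return best if 2 * best_ov > n else None


def deduplicate_hits(hits: list[G4Hit]) -> list[G4Hit]:
    """Collapse isoform-redundant hits.

    Uniqueness key is (gene, matched sequence, region kind); the first
    occurrence in input order is kept, annotated with the number of collapsed
    duplicates via ``multiplicity``.
    """
    out: list[G4Hit] = []
    index: dict[tuple[str, str, str], G4Hit] = {}
    for hit in hits:
        key = (hit.gene, hit.sequence, hit.region_kind)
        if key in index:
            index[key].multiplicity += hit.multiplicity
        else:
            kept = replace(hit)
            index[key] = kept
            out.append(kept)
    return out


TSV_COLUMNS = [
    "accession",
    "gene",
    "region_kind",
    "utr_position",
    "length",
    "loop_class",
    "track1",
    "track2",
    "track3",
    "track4",
    "loop1",
    "loop2",
    "loop3",
    "sequence",
    "cgcc_score",
    "multiplicity",
]


def _fmt(value) -> str:
    if value is None or value == "":
        return "."
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_hits(
    hits: list[G4Hit],
    path,
    format: str = "tsv",
    header_comments: list[str] | None = None,
) -> None:
    """Write hits as TSV (decomposition columns) or BED6 (transcript space)."""
    if format not in ("tsv", "bed"):
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"#{line}\n")
        if format == "tsv":
            fh.write("\t".join(TSV_COLUMNS) + "\n")
            for h in hits:
                row = [
                    h.transcript_accession,
                    h.gene,
                    h.region_kind,
                    h.utr_position,
                    h.end - h.start,
                    h.loop_class,
                    *(h.track_seq(i) for i in range(4)),
                    *(h.loop_seq(i) for i in range(3)),
                    h.sequence,
                    h.cgcc_score,
                    h.multiplicity,
                ]
                fh.write("\t".join(_fmt(v) for v in row) + "\n")
        else:
            for h in hits:
                if h.cgcc_score is None:
                    score = 0
                elif h.cgcc_score == float("inf"):
                    score = 1000
                else:
                    score = min(1000, round(100 * h.cgcc_score))
                name = f"{h.gene or '.'}|{h.loop_class}"
                fh.write(
                    f"{h.transcript_accession}\t{h.start}\t{h.end}\t"
                    f"{name}\t{score}\t+\n"
                )
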