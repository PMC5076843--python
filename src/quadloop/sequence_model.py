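"""Transcript data model, alphabet handling and UTR coordinate conventions.

Transcripts are modelled as a single spliced RNA sequence with 0-based
half-open CDS boundaries; the 5'-UTR is ``[0, cds_start)`` and the 3'-UTR is
``[cds_end, len)``.  User-facing coordinates inside a UTR use a signed 1-based
convention: the first UTR nucleotide is position 1, the nucleotide immediately
upstream is position -1, and there is no position 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Sentinel for IUPAC ambiguity codes in permissive mode.  ``N`` can never be
#: part of a G-track or a C-run, and counts as a generic loop nucleotide.
AMBIGUOUS_SENTINEL = "N"

_RNA_BASES = frozenset("ACGU")
_ACCEPTED = frozenset("ACGTUacgtu")
_IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVNryswkmbdhvn")


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside the RNA alphabet."""


def normalize_alphabet(raw: str, permissive: bool = False) -> str:
    """Normalize a nucleotide string to uppercase RNA over ``{A,C,G,U}``.

    ``T`` is mapped to ``U``.  Any other character raises
    :class:`AlphabetError` naming the offending 1-based position.  With
    ``permissive=True`` IUPAC ambiguity codes are mapped to
    :data:`AMBIGUOUS_SENTINEL` instead of raising.
    """
    if not raw:
        raise AlphabetError("empty sequence")
    out = []
    for i, ch in enumerate(raw):
        if ch in _ACCEPTED:
            up = ch.upper()
            out.append("U" if up == "T" else up)
        elif permissive and ch in _IUPAC_AMBIGUITY:
            out.append(AMBIGUOUS_SENTINEL)
        else:
            raise AlphabetError(
                f"invalid character {ch!r} at position {i + 1}"
            )
    return "".join(out)


@dataclass
class TranscriptRecord:
    """A transcript sequence plus CDS boundaries defining its UTRs."""

    accession: str
    gene: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start <= self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{self.accession}: CDS bounds [{self.cds_start}, "
                f"{self.cds_end}) do not fit sequence of length "
                f"{len(self.sequence)}"
            )
        bad = set(self.sequence) - _RNA_BASES - {AMBIGUOUS_SENTINEL}
        if bad:
            raise AlphabetError(
                f"{self.accession}: non-normalized characters {sorted(bad)}; "
                "pass sequences through normalize_alphabet first"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def utr5(self) -> "Region":
        return Region(self.accession, 0, self.cds_start, "utr5")

    @property
    def utr3(self) -> "Region":
        return Region(self.accession, self.cds_end, len(self.sequence), "utr3")

    @property
    def cds(self) -> "Region":
        return Region(self.accession, self.cds_start, self.cds_end, "cds")

    def regions(self) -> list["Region"]:
        """Non-empty regions tiling ``[0, len)`` in 5'→3' order."""
        return [r for r in (self.utr5, self.cds, self.utr3) if r.end > r.start]


@dataclass(frozen=True)
class Region:
    """A half-open interval of a transcript, tagged utr5/cds/utr3.

    Unlike transcript regions produced by :meth:`TranscriptRecord.regions`,
    a free-standing Region may be empty only when derived from a transcript
    whose corresponding segment is empty.
    """

    transcript_accession: str
    start: int
    end: int
    kind: str  # utr5 | cds | utr3

    def __post_init__(self) -> None:
        if self.kind not in ("utr5", "cds", "utr3"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError("region start must not exceed end")

    def __len__(self) -> int:
        return self.end - self.start


def utr_position(region: Region, transcript_offset: int) -> int:
    """Signed 1-based position of a transcript offset relative to a UTR start.

    The first nucleotide of the UTR is 1; offsets upstream count back from -1
    with no position 0, so an offset 6 nt before the UTR start reports -6.
    """
    if region.kind not in ("utr5", "utr3"):
        raise ValueError("utr_position requires a utr5 or utr3 region")
    delta = transcript_offset - region.start
    return delta + 1 if delta >= 0 else delta


def _parse_header_fallback(header: str) -> tuple[str, str, int, int] | None:
    # convenience format: accession|gene|cds_start..cds_end
    parts = header.split("|")
    if len(parts) != 3 or ".." not in parts[2]:
        return None
    lo, _, hi = parts[2].partition("..")
    try:
        return parts[0], parts[1], int(lo), int(hi)
    except ValueError:
        return None


def read_annotation(path: str | Path) -> dict[str, tuple[str, int, int]]:
    """Read the annotation TSV (accession, gene, cds_start, cds_end)."""
    table: dict[str, tuple[str, int, int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["accession", "gene", "cds_start", "cds_end"]
        if header != expected:
            raise ValueError(
                f"annotation header {header} != expected {expected}"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            acc, gene, lo, hi = line.split("\t")
            table[acc] = (gene, int(lo), int(hi))
    return table


def read_transcripts(
    fasta_path: str | Path,
    annotation_path: str | Path | None = None,
    permissive: bool = False,
) -> list[TranscriptRecord]:
    """Load transcripts from FASTA plus a CDS annotation table.

    FASTA records without an annotation row are skipped with a warning.  When
    ``annotation_path`` is None, CDS bounds are parsed from headers of the
    form ``accession|gene|cds_start..cds_end``.
    """
    annotation = read_annotation(annotation_path) if annotation_path else None
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if annotation is not None:
            acc = rec.id
            if acc not in annotation:
                logger.warning("no annotation for %s; record skipped", acc)
                warnings.warn(f"no annotation for {acc}; record skipped")
                continue
            gene, cds_start, cds_end = annotation[acc]
        else:
            parsed = _parse_header_fallback(rec.description)
            if parsed is None:
                logger.warning(
                    "header %r not parseable; record skipped", rec.description
                )
                warnings.warn(f"header {rec.description!r} not parseable")
                continue
            acc, gene, cds_start, cds_end = parsed
        if acc in seen:
            raise ValueError(f"duplicate FASTA record id {acc}")
        seen.add(acc)
        seq = normalize_alphabet(str(rec.seq), permissive=permissive)
        records.append(TranscriptRecord(acc, gene, seq, cds_start, cds_end))
    return records


def write_transcripts(
    records: Iterable[TranscriptRecord],
    fasta_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Write transcripts back to FASTA + annotation TSV (round-trip exact)."""
    records = list(records)
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records),
        str(fasta_path),
        "fasta",
    )
    with open(annotation_path, "w") as fh:
        fh.write("accession\tgene\tcds_start\tcds_end\n")
        for r in records:
            fh.write(f"{r.accession}\t{r.gene}\t{r.cds_start}\t{r.cds_end}\n")
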