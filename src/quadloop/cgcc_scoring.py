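"""Consecutive-G over consecutive-C (cG/cC) fold-propensity scoring.

Each residue inside a maximal G-run (resp. C-run) of length L contributes a
weight of 10·min(L, 3): an isolated G counts 10, each G of a GG doublet 20,
and each G of a run of three or more 30; mirrored for C.  The score is the
ratio of the G-sum over the C-sum computed on the PG4 hit extended by up to
25 nt of transcript context on each side.

Scores >= 3.05 predict folding, <= 2.05 predict no folding, and the band in
between is an ambiguous call.  A window without any C yields an explicit
"no-C" sentinel (+inf) and is classified as likely folded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .g4_scanner import G4Hit
from .sequence_model import TranscriptRecord, normalize_alphabet

DEFAULT_FLANK = 25
FOLDED_THRESHOLD = 3.05
UNLIKELY_THRESHOLD = 2.05

#: Sentinel score for windows without any cytosine.
NO_C_SENTINEL = math.inf

WEIGHT_CAP = 3  # run-length saturation of the per-residue weight


def run_decomposition(seq: str, base: str) -> list[tuple[int, int]]:
    """Maximal runs of ``base`` as (offset, run_length), ordered 5'→3'."""
    if base not in ("G", "C"):
        raise ValueError("base must be 'G' or 'C'")
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == base:
            j = i
            while j < n and seq[j] == base:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def residue_weight(run_length: int) -> int:
    """Per-residue weight for a residue inside a maximal run of given length."""
    return 10 * min(run_length, WEIGHT_CAP)


def _run_sum(seq: str, base: str) -> int:
    return sum(L * residue_weight(L) for _, L in run_decomposition(seq, base))


@dataclass(frozen=True)
class ScoreWindow:
    """A PG4 hit sequence extended by transcript flanks (up to 25 nt each)."""

    sequence: str
    flank_up_len: int = 0
    flank_down_len: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty score window")
        if self.flank_up_len < 0 or self.flank_down_len < 0:
            raise ValueError("flank lengths must be non-negative")
        if self.flank_up_len + self.flank_down_len >= len(self.sequence):
            raise ValueError("flanks leave no room for the hit")

    @property
    def hit_sequence(self) -> str:
        end = len(self.sequence) - self.flank_down_len
        return self.sequence[self.flank_up_len : end]


@dataclass(frozen=True)
class CgCcResult:
    cG: float
    cC: float
    score: float  # +inf == no-C sentinel
    classification: str  # likely_folded | ambiguous | unlikely

    @property
    def score_display(self) -> str:
        return "> max" if math.isinf(self.score) else f"{self.score:.2f}"


def classify_score(score: float) -> str:
    """Thresholds are inclusive toward their named class."""
    if score >= FOLDED_THRESHOLD:
        return "likely_folded"
    if score <= UNLIKELY_THRESHOLD:
        return "unlikely"
    return "ambiguous"


def cgcc_score(window: ScoreWindow | str) -> CgCcResult:
    """Score a window; accepts a raw (already normalized) string for CLI use."""
    seq = window if isinstance(window, str) else window.sequence
    if not seq:
        raise ValueError("empty sequence")
    cg = _run_sum(seq, "G")
    cc = _run_sum(seq, "C")
    score = cg / cc if cc > 0 else NO_C_SENTINEL
    return CgCcResult(cG=cg, cC=cc, score=score, classification=classify_score(score))


def build_window(
    hit: G4Hit, record: TranscriptRecord, flank: int = DEFAULT_FLANK
) -> ScoreWindow:
    """Extend a hit by up to ``flank`` nt of transcript sequence on each side.

    Flanks are truncated silently at transcript ends; achieved lengths are
    recorded on the window.
    """
    up = min(flank, hit.start)
    down = min(flank, len(record.sequence) - hit.end)
    seq = record.sequence[hit.start - up : hit.end + down]
    return ScoreWindow(sequence=seq, flank_up_len=up, flank_down_len=down)


def score_hit(
    hit: G4Hit, record: TranscriptRecord, flank: int = DEFAULT_FLANK
) -> CgCcResult:
    return cgcc_score(build_window(hit, record, flank))


def score_raw(sequence: str) -> CgCcResult:
    """Score a raw sequence treating the whole record as the window."""
    return cgcc_score(normalize_alphabet(sequence))
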