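"""Exhaustive-tiling reference parser.

Independent of the regex-based scanner in :mod:`quadloop.g4_scanner`: it
enumerates every loop-length tiling satisfying a pattern (tracks take exactly
``min_track_len`` guanines), orders parses lexicographically ascending on
(start, |L1|, |L2|, |L3|), and takes the first.  Deliberately brute force;
used as the ground truth in property tests and to normalize planted-motif
truth tables.
"""

from __future__ import annotations

from .g4_scanner import G4Hit, PatternSpec, classify_hit


def _is_track(seq: str, pos: int, x: int) -> bool:
    """True iff ``x`` guanines sit at ``pos`` (run may extend further)."""
    if pos + x > len(seq):
        return False
    return all(ch == "G" for ch in seq[pos : pos + x])


def _first_parse(seq: str, start: int, pattern: PatternSpec):
    """Lexicographically first complete tiling anchored at ``start``, or None."""
    x = pattern.min_track_len
    (l1lo, l1hi), (l2lo, l2hi), (l3lo, l3hi) = pattern.loop_bounds

    if not _is_track(seq, start, x):
        return None
    for l1 in range(l1lo, l1hi + 1):
        p2 = start + x + l1
        if not _is_track(seq, p2, x):
            continue
        for l2 in range(l2lo, l2hi + 1):
            p4 = p2 + x + l2
            if not _is_track(seq, p4, x):
                continue
            for l3 in range(l3lo, l3hi + 1):
                p6 = p4 + x + l3
                if _is_track(seq, p6, x):
                    return (x, l1, x, l2, x, l3, x)
    return None


def exhaustive_scan(seq: str, pattern: PatternSpec) -> list[G4Hit]:
    """Non-overlapping scan built on the brute-force first-parse search."""
    hits: list[G4Hit] = []
    pos = 0
    n = len(seq)
    while pos < n:
        found = None
        for start in range(pos, n):
            parse = _first_parse(seq, start, pattern)
            if parse is not None:
                found = (start, parse)
                break
        if found is None:
            break
        start, lengths = found
        bounds = []
        p = start
        for length in lengths:
            bounds.append((p, p + length))
            p += length
        hit = G4Hit(
            start=start,
            end=p,
            tracks=tuple(bounds[0::2]),
            loops=tuple(bounds[1::2]),
            sequence=seq[start:p],
            pattern_name=pattern.name,
        )
        hit.loop_class = classify_hit(hit)
        hits.append(hit)
        pos = p
    return hits
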