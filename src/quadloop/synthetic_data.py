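"""Seeded generators for every input the toolkit consumes, with ground truth.

Three generators cover the pipeline end to end:

* :func:`generate_transcriptome` — random transcripts with planted G4 motifs
  and a truth table of their exact spans and decompositions;
* :func:`generate_probing_experiment` — K+/Li+ lane profiles with
  loop-elevated ratios for folded wild-type constructs;
* :func:`generate_reporter_data` — dual-luciferase wells with a known true
  WT/mutant fold change.

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .g4_scanner import BUILTIN_PATTERNS, G4Hit, PatternSpec, classify_hit
from .oracle import exhaustive_scan
from .probing_analysis import LaneProfile
from .reporter_stats import LuciferaseWell
from .sequence_model import TranscriptRecord, write_transcripts

#: Guard distance around a planted motif kept free of competing G-runs.
#: 40 (max loop) + 3 (track) + 1 ensures no background G-run can anchor a
#: match that reaches into the plant.
GUARD = 44

MIN_UTR_LEN = 30
_NON_G = np.array(list("ACU"))


@dataclass(frozen=True)
class PlantSpec:
    """Geometry of a motif to plant: four track lengths and three loops."""

    track_lengths: tuple[int, int, int, int] = (3, 3, 3, 3)
    loop_lengths: tuple[int, int, int] = (1, 1, 1)
    loop_composition: str = "no_g_runs"  # no_g_runs | adversarial_g_runs
    region: str = "utr3"  # utr5 | utr3
    position: int | None = None  # 0-based offset within the UTR

    def __post_init__(self) -> None:
        if any(t < 3 for t in self.track_lengths):
            raise ValueError("track lengths must be >= 3")
        if self.loop_composition not in ("no_g_runs", "adversarial_g_runs"):
            raise ValueError(f"unknown loop composition {self.loop_composition!r}")
        if self.region not in ("utr5", "utr3"):
            raise ValueError("region must be utr5 or utr3")
        if self.matching_pattern() is None and self.loop_composition == "no_g_runs":
            raise ValueError(
                f"loop lengths {self.loop_lengths} fit no built-in pattern"
            )

    def matching_pattern(self) -> PatternSpec | None:
        for pattern in BUILTIN_PATTERNS.values():
            if all(
                lo <= L <= hi
                for L, (lo, hi) in zip(self.loop_lengths, pattern.loop_bounds)
            ):
                return pattern
        return None

    @property
    def total_length(self) -> int:
        return sum(self.track_lengths) + sum(self.loop_lengths)


@dataclass(frozen=True)
class TruthRow:
    """One planted hit: where it is and how it decomposes."""

    transcript_accession: str
    start: int
    end: int
    track_lengths: tuple[int, ...]
    loop_lengths: tuple[int, ...]
    sequence: str
    loop_class: str


@dataclass
class SyntheticTranscriptome:
    transcripts: list[TranscriptRecord]
    truth: list[TruthRow]
    edit_log: list[str] = field(default_factory=list)

    def write(self, outdir: str | Path, prefix: str = "synthetic") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / f"{prefix}.fasta"
        annotation = outdir / f"{prefix}.annotation.tsv"
        truth = outdir / f"{prefix}.truth.tsv"
        write_transcripts(self.transcripts, fasta, annotation)
        with open(truth, "w") as fh:
            fh.write(
                "accession\tstart\tend\ttrack_lengths\tloop_lengths\t"
                "loop_class\tsequence\n"
            )
            for row in self.truth:
                fh.write(
                    f"{row.transcript_accession}\t{row.start}\t{row.end}\t"
                    f"{','.join(map(str, row.track_lengths))}\t"
                    f"{','.join(map(str, row.loop_lengths))}\t"
                    f"{row.loop_class}\t{row.sequence}\n"
                )
        return {"fasta": fasta, "annotation": annotation, "truth": truth}


def _random_sequence(rng: np.random.Generator, n: int, gc_fraction: float) -> str:
    probs = [
        (1 - gc_fraction) / 2,  # A
        gc_fraction / 2,  # C
        gc_fraction / 2,  # G
        (1 - gc_fraction) / 2,  # U
    ]
    return "".join(rng.choice(list("ACGU"), size=n, p=probs))

def _plant_string(spec: PlantSpec, rng: np.random.Generator, gc_fraction: float) -> str:
    parts = []
    for i, t in enumerate(spec.track_lengths):
        parts.append("G" * t)
        if i < 3:
            L = spec.loop_lengths[i]
            if spec.loop_composition == "no_g_runs":
                # G-free loops guarantee the planted parse is the lazy parse
                loop = "".join(rng.choice(_NON_G, size=L))
            else:
                loop = _random_sequence(rng, L, max(gc_fraction, 0.5))
            parts.append(loop)
    return "".join(parts)


def _normalized_truth(
    plant: str, spec: PlantSpec, accession: str, offset: int
) -> TruthRow:
    """Truth is the exhaustive-oracle parse of the isolated plant string.

    For track lengths of exactly 3 and G-free loops this equals the plant
    spec; surplus guanines (longer tracks, adversarial loops) are folded into
    loops the same way any scanner honouring lazy semantics must fold them.
    """
    pattern = spec.matching_pattern() or BUILTIN_PATTERNS["PLL1"]
    hits = exhaustive_scan(plant, pattern)
    if not hits:
        raise ValueError(f"plant {spec} does not scan as a motif")
    hit = hits[0]
    return TruthRow(
        transcript_accession=accession,
        start=offset + hit.start,
        end=offset + hit.end,
        track_lengths=hit.track_lengths,
        loop_lengths=hit.loop_lengths,
        sequence=hit.sequence,
        loop_class=hit.loop_class,
    )


def _edit_guard_zone(
    seq: list[str],
    lo: int,
    hi: int,
    protected: set[int],
    rng: np.random.Generator,
    log: list[str],
    accession: str,
) -> None:
    """Break up G-runs >= 3 within [lo, hi), never touching protected spans."""
    lo = max(0, lo)
    hi = min(len(seq), hi)
    i = lo
    while i < hi:
        if seq[i] == "G" and i not in protected:
            j = i
            while j < len(seq) and seq[j] == "G" and j not in protected:
                j += 1
            if j - i >= 3:
                for k in range(i + 2, j, 3):
                    old = seq[k]
                    seq[k] = str(rng.choice(_NON_G))
                    log.append(f"{accession}: broke G-run at {k} ({old}->{seq[k]})")
            i = j
        else:
            i += 1


def generate_transcriptome(
    n_transcripts: int,
    length_range: tuple[int, int],
    gc_fraction: float,
    plants: list[PlantSpec],
    seed: int,
) -> SyntheticTranscriptome:
    """Random transcripts with planted motifs and an exact truth table.

    Plants are assigned to transcripts round-robin.  In ``no_g_runs`` mode
    the neighbourhood of each plant is rejection-edited: the bases adjacent
    to the plant are forced non-G and background G-runs of three or more
    within ``GUARD`` nt of a plant boundary are broken, so the scanner is
    guaranteed to recover each planted decomposition exactly.
    """
    if n_transcripts < 1:
        raise ValueError("need at least one transcript")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    records: list[TranscriptRecord] = []
    truth: list[TruthRow] = []
    edit_log: list[str] = []

    plants_by_transcript: dict[int, list[PlantSpec]] = {}
    for i, spec in enumerate(plants):
        plants_by_transcript.setdefault(i % n_transcripts, []).append(spec)

    for t in range(n_transcripts):
        accession = f"SYN{t + 1:06d}"
        gene = f"SYNGENE{t + 1}"
        n = int(rng.integers(lo, hi + 1))
        my_plants = plants_by_transcript.get(t, [])
        min_len = 3 * MIN_UTR_LEN + sum(p.total_length + 2 * GUARD for p in my_plants)
        if n < min_len:
            raise ValueError(
                f"transcript {accession} of length {n} cannot accommodate "
                f"its plants (needs >= {min_len} nt)"
            )
        seq = list(_random_sequence(rng, n, gc_fraction))

        # CDS bounds leaving both UTRs at least MIN_UTR_LEN nt, with room
        # for the requested plants
        utr5_need = max(
            MIN_UTR_LEN,
            sum(p.total_length + 2 * GUARD for p in my_plants if p.region == "utr5"),
        )
        utr3_need = max(
            MIN_UTR_LEN,
            sum(p.total_length + 2 * GUARD for p in my_plants if p.region == "utr3"),
        )
        if utr5_need + utr3_need + MIN_UTR_LEN > n:
            raise ValueError(f"transcript {accession} too short for its plants")
        cds_start = int(rng.integers(utr5_need, n - utr3_need - MIN_UTR_LEN + 1))
        cds_end = int(rng.integers(cds_start + 1, n - utr3_need + 1))

        protected: set[int] = set()
        cursor = {"utr5": 0, "utr3": cds_end}
        limit = {"utr5": cds_start, "utr3": n}
        for spec in my_plants:
            plant = _plant_string(spec, rng, gc_fraction)
            L = len(plant)
            region_lo, region_hi = cursor[spec.region], limit[spec.region]
            if spec.position is not None:
                start = (0 if spec.region == "utr5" else cds_end) + spec.position
                if not (region_lo <= start and start + L <= region_hi):
                    raise ValueError(
                        f"plant at position {spec.position} does not fit "
                        f"{spec.region} of {accession}"
                    )
            else:
                space = region_hi - region_lo - L - GUARD
                if space < GUARD:
                    raise ValueError(f"plant does not fit {spec.region} of {accession}")
                start = region_lo + int(rng.integers(GUARD, space + 1))
            seq[start : start + L] = list(plant)
            protected.update(range(start, start + L))
            cursor[spec.region] = start + L + GUARD

            if spec.loop_composition == "no_g_runs":
                if start > 0 and seq[start - 1] == "G":
                    seq[start - 1] = str(rng.choice(_NON_G))
                    edit_log.append(f"{accession}: cleared G at {start - 1} (plant flank)")
                if start + L < n and seq[start + L] == "G":
                    seq[start + L] = str(rng.choice(_NON_G))
                    edit_log.append(f"{accession}: cleared G at {start + L} (plant flank)")
                _edit_guard_zone(seq, start - GUARD, start, protected, rng, edit_log, accession)
                _edit_guard_zone(seq, start + L, start + L + GUARD, protected, rng, edit_log, accession)

            truth.append(_normalized_truth(plant, spec, accession, start))

        records.append(TranscriptRecord(accession, gene, "".join(seq), cds_start, cds_end))

    return SyntheticTranscriptome(records, truth, edit_log)


def generate_probing_experiment(
    decomposition: G4Hit | tuple[str, frozenset[int], frozenset[int]],
    folded: bool,
    noise_sigma: float = 0.25,
    loop_ratio: float = 3.0,
    seed: int = 0,
    n_replicates: int = 2,
) -> dict[tuple[str, str], list[LaneProfile]]:
    """Lane profiles (WT/mutant × K/Li × replicates) for one experiment.

    Li+ lanes are lognormal around a common unit baseline; K+ lanes are
    multiplied by ``loop_ratio`` at loop positions iff the construct is the
    wild type and ``folded`` is true.  The mutant never folds.
    """
    if isinstance(decomposition, G4Hit):
        sequence = decomposition.sequence
        loop_positions = decomposition.loop_offsets
    else:
        sequence, loop_positions, _tracks = decomposition
    n = len(sequence)
    rng = np.random.default_rng(seed)
    boost = np.ones(n)
    boost[list(loop_positions)] = loop_ratio

    lanes: dict[tuple[str, str], list[LaneProfile]] = {}
    for construct in ("WT", "mutant"):
        for cation in ("K", "Li"):
            lanes[(construct, cation)] = []
            for rep in range(1, n_replicates + 1):
                base = np.exp(rng.normal(0.0, noise_sigma, size=n)) if noise_sigma > 0 else np.ones(n)
                signal = base.copy()
                if cation == "K" and construct == "WT" and folded:
                    signal = signal * boost
                lanes[(construct, cation)].append(
                    LaneProfile(construct, cation, rep, signal)
                )
    return lanes


def generate_reporter_data(
    true_fold: float,
    cv: float,
    n_days: int = 3,
    n_tech: int = 3,
    seed: int = 0,
    fluc_scale: float = 1e6,
) -> list[LuciferaseWell]:
    """Luciferase wells with mutant ratio 1.0 and WT ratio ``true_fold``.

    Lognormal multiplicative noise is applied at both the day and the
    technical-replicate level, each with the given coefficient of variation.
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be positive")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    wells: list[LuciferaseWell] = []
    for construct, center in (("WT", true_fold), ("mutant", 1.0)):
        for day in range(1, n_days + 1):
            day_eff = np.exp(rng.normal(0.0, sigma)) if cv > 0 else 1.0
            for tech in range(1, n_tech + 1):
                tech_eff = np.exp(rng.normal(0.0, sigma)) if cv > 0 else 1.0
                ratio = center * day_eff * tech_eff
                wells.append(
                    LuciferaseWell(construct, day, tech, ratio * fluc_scale, fluc_scale)
                )
    return wells
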