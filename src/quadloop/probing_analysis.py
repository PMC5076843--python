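"""In-line probing ratio analysis: K+/Li+ band-intensity profiles and
folded/unfolded calls.

Band intensities come from quantified gel lanes, one value per nucleotide
(5'→3').  For each replicate the K+ lane is divided elementwise by the Li+
lane; the per-nucleotide mean and SD across replicates form the ratio
profile.  A construct is called folded when at least one loop nucleotide of
the wild type reaches the threshold (default 2.0) while no loop nucleotide of
the G/A mutant does.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_THRESHOLD = 2.0

CONSTRUCTS = ("WT", "mutant")
CATIONS = ("K", "Li")


@dataclass
class LaneProfile:
    construct: str  # WT | mutant
    cation: str  # K | Li
    replicate: int
    intensities: np.ndarray

    def __post_init__(self) -> None:
        if self.construct not in CONSTRUCTS:
            raise ValueError(f"construct must be one of {CONSTRUCTS}")
        if self.cation not in CATIONS:
            raise ValueError(f"cation must be one of {CATIONS}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ValueError("intensities must be one-dimensional")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


def normalize_lane(lane: LaneProfile, mode: str = "total") -> LaneProfile:
    """Scale a lane so intensities sum to 1 (mode='total') or pass through."""
    if mode == "none":
        return lane
    if mode != "total":
        raise ValueError(f"unknown normalization mode {mode!r}")
    total = float(lane.intensities.sum())
    if total <= 0:
        raise ValueError("cannot normalize an all-zero lane")
    return LaneProfile(
        lane.construct, lane.cation, lane.replicate, lane.intensities / total
    )


@dataclass
class RatioProfile:
    """Per-nucleotide mean ± SD of K+/Li+ ratios over replicates.

    Positions where any Li intensity is zero carry NaN and are excluded from
    folding calls.
    """

    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int
    sequence: str = ""
    loop_positions: frozenset[int] = frozenset()
    track_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.loop_positions & self.track_positions:
            raise ValueError("loop and track position sets must be disjoint")
        n = len(self.mean)
        for pos_set in (self.loop_positions, self.track_positions):
            if any(p < 0 or p >= n for p in pos_set):
                raise ValueError("annotated position outside profile")


def ratio_profile(
    k_lanes: list[LaneProfile],
    li_lanes: list[LaneProfile],
    normalize: str = "none",
    sequence: str = "",
    loop_positions: frozenset[int] = frozenset(),
    track_positions: frozenset[int] = frozenset(),
) -> RatioProfile:
    """Pair K+/Li+ lanes by replicate and aggregate per-nucleotide ratios.

    ``normalize`` is applied per lane before dividing ('none' assumes lanes
    were loaded with equivalent total signal, the experimental convention;
    'total' rescales each lane to unit sum, making ratios invariant to
    per-lane scaling).
    """
    k_by_rep = {lane.replicate: lane for lane in k_lanes}
    li_by_rep = {lane.replicate: lane for lane in li_lanes}
    shared = sorted(set(k_by_rep) & set(li_by_rep))
    if not shared:
        raise ValueError("no K/Li lane pairs share a replicate number")
    if len(shared) < 2:
        warnings.warn("only one replicate; SD undefined")
    lengths = {len(k_by_rep[r].intensities) for r in shared} | {
        len(li_by_rep[r].intensities) for r in shared
    }
    if len(lengths) != 1:
        raise ValueError(f"lanes have mismatched lengths: {sorted(lengths)}")
    ratios = []
    for rep in shared:
        k = normalize_lane(k_by_rep[rep], normalize).intensities
        li = normalize_lane(li_by_rep[rep], normalize).intensities
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(li > 0, k / np.where(li > 0, li, 1.0), np.nan)
        ratios.append(r)
    stack = np.vstack(ratios)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = (
            np.nanstd(stack, axis=0, ddof=1)
            if len(shared) > 1
            else np.full(stack.shape[1], np.nan)
        )
    return RatioProfile(
        mean=mean,
        sd=sd,
        n_replicates=len(shared),
        sequence=sequence,
        loop_positions=loop_positions,
        track_positions=track_positions,
    )


@dataclass(frozen=True)
class FoldingCall:
    verdict: str  # folded | not_folded | inconclusive
    supporting_positions: tuple[int, ...]
    threshold: float

    def __post_init__(self) -> None:
        if self.verdict == "folded" and not self.supporting_positions:
            raise ValueError("folded verdict requires supporting positions")


def _responsive_loops(profile: RatioProfile, threshold: float) -> list[int]:
    return sorted(
        p
        for p in profile.loop_positions
        if not np.isnan(profile.mean[p]) and profile.mean[p] >= threshold
    )


def call_folding(
    wt: RatioProfile,
    mut: RatioProfile | None,
    threshold: float = DEFAULT_THRESHOLD,
    min_loop_count: int = 1,
) -> FoldingCall:
    """Threshold rule: folded iff >= ``min_loop_count`` WT loop nucleotides
    reach the threshold and no mutant loop nucleotide does; not_folded iff the
    WT shows none; inconclusive when the mutant is also responsive."""
    if not wt.loop_positions:
        raise ValueError("WT profile has no annotated loop positions")
    if all(np.isnan(wt.mean[p]) for p in wt.loop_positions):
        raise ValueError("ratio undefined at every WT loop position")
    wt_support = _responsive_loops(wt, threshold)
    if len(wt_support) < min_loop_count:
        return FoldingCall("not_folded", (), threshold)
    if mut is not None and _responsive_loops(mut, threshold):
        return FoldingCall("inconclusive", (), threshold)
    return FoldingCall("folded", tuple(wt_support), threshold)


# ---------------------------------------------------------------------------
# I/O: long-format lane tables and result export
# ---------------------------------------------------------------------------

LANE_TABLE_COLUMNS = ["position", "nucleotide", "construct", "cation", "replicate", "intensity"]


def read_lane_table(path: str | Path) -> tuple[dict, str]:
    """Read a long-format delimited lane table.

    Returns ``(lanes, sequence)`` where ``lanes`` maps (construct, cation) to
    a list of LaneProfile and ``sequence`` is rebuilt from the nucleotide
    column (empty if absent). Positions are 0-based and must be contiguous.
    """
    rows = []
    with open(path) as fh:
        sample = fh.readline()
        delim = "\t" if sample.count("\t") >= sample.count(",") else ","
        fh.seek(0)
        for row in csv.DictReader(fh, delimiter=delim):
            rows.append(row)
    if not rows:
        raise ValueError(f"empty lane table: {path}")
    missing = set(LANE_TABLE_COLUMNS[2:]) - set(rows[0]) | {"position", "intensity"} - set(rows[0])
    if missing:
        raise ValueError(f"lane table missing columns: {sorted(missing)}")
    grouped: dict[tuple[str, str, int], dict[int, float]] = {}
    seq_chars: dict[int, str] = {}
    for row in rows:
        key = (row["construct"], row["cation"], int(row["replicate"]))
        pos = int(row["position"])
        grouped.setdefault(key, {})[pos] = float(row["intensity"])
        if row.get("nucleotide"):
            seq_chars[pos] = row["nucleotide"]
    lanes: dict[tuple[str, str], list[LaneProfile]] = {}
    for (construct, cation, rep), values in sorted(grouped.items()):
        positions = sorted(values)
        if positions != list(range(len(positions))):
            raise ValueError(
                f"lane {(construct, cation, rep)} has non-contiguous positions"
            )
        lanes.setdefault((construct, cation), []).append(
            LaneProfile(construct, cation, rep, np.array([values[p] for p in positions]))
        )
    sequence = "".join(seq_chars[p] for p in sorted(seq_chars)) if seq_chars else ""
    return lanes, sequence


def write_ratio_table(profile: RatioProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tnucleotide\trole\tmean_ratio\tsd\n")
        for i in range(len(profile.mean)):
            nt = profile.sequence[i] if i < len(profile.sequence) else "."
            role = (
                "loop"
                if i in profile.loop_positions
                else "track" if i in profile.track_positions else "."
            )
            mean = "." if np.isnan(profile.mean[i]) else f"{profile.mean[i]:.4f}"
            sd = "." if np.isnan(profile.sd[i]) else f"{profile.sd[i]:.4f}"
            fh.write(f"{i}\t{nt}\t{role}\t{mean}\t{sd}\n")


def write_verdict(call: FoldingCall, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "verdict": call.verdict,
                "threshold": call.threshold,
                "supporting_positions": list(call.supporting_positions),
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def plot_ratio_histogram(
    wt: RatioProfile, mut: RatioProfile | None, path: str | Path, threshold: float = DEFAULT_THRESHOLD
) -> None:
    """Bar chart of per-nucleotide K+/Li+ ratios (WT vs mutant)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(wt.mean)
    x = np.arange(n)
    fig, ax = plt.subplots(figsize=(max(6, n * 0.25), 4))
    width = 0.4 if mut is not None else 0.8
    ax.bar(x - width / 2 * (mut is not None), wt.mean, width, yerr=np.nan_to_num(wt.sd), label="WT", color="tab:blue")
    if mut is not None:
        ax.bar(x + width / 2, mut.mean, width, yerr=np.nan_to_num(mut.sd), label="G/A mutant", color="tab:red")
    ax.axhline(threshold, linestyle=":", color="black")
    if wt.sequence:
        ax.set_xticks(x)
        ax.set_xticklabels(list(wt.sequence), fontsize=6)
    ax.set_ylabel("K+/Li+ ratio")
    ax.set_xlabel("nucleotide")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
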