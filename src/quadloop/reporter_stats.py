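"""Dual-luciferase fold-change statistics and the qPCR mRNA-level control.

The reporter readout is the Renilla/Firefly ratio per well.  Technical
replicates are averaged within each (construct, day) first; the fold change
is the mean of WT day-means divided by the mean of mutant day-means, and
significance comes from an unpaired equal-variance Student's t test on the
day-level ratios.  The qPCR control is, literally, a ratio of mean threshold
cycles (Rluc/Fluc per construct, then WT over mutant); a conventional
2^-ddCt mode is available behind a flag but is never the default.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class LuciferaseWell:
    construct: str  # WT | mutant
    day: int
    tech_rep: int
    rluc: float
    fluc: float

    def __post_init__(self) -> None:
        if self.construct not in ("WT", "mutant"):
            raise ValueError("construct must be 'WT' or 'mutant'")
        if self.fluc <= 0:
            raise ValueError("fluc must be positive")
        if self.rluc < 0:
            raise ValueError("rluc must be non-negative")

    @property
    def ratio(self) -> float:
        return self.rluc / self.fluc


@dataclass(frozen=True)
class ReporterResult:
    fold: float
    p_value: float  # NaN when undefined (single day)
    stars: str  # ns | * | ** | *** | ****
    n_days: int


@dataclass(frozen=True)
class QpcrRecord:
    target: str  # Rluc | Fluc
    construct: str  # WT | mutant
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if self.target not in ("Rluc", "Fluc"):
            raise ValueError("target must be 'Rluc' or 'Fluc'")
        if self.construct not in ("WT", "mutant"):
            raise ValueError("construct must be 'WT' or 'mutant'")
        if self.ct <= 0:
            raise ValueError("ct must be positive")


def significance_stars(p_value: float) -> str:
    if math.isnan(p_value):
        return "ns"
    if p_value < 0.0001:
        return "****"
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def day_means(wells: list[LuciferaseWell], construct: str) -> list[float]:
    """Average the technical replicates of one construct within each day."""
    by_day: dict[int, list[float]] = {}
    for w in wells:
        if w.construct == construct:
            by_day.setdefault(w.day, []).append(w.ratio)
    return [float(np.mean(v)) for _, v in sorted(by_day.items())]


def luciferase_fold(
    wells: list[LuciferaseWell], unit: str = "day"
) -> ReporterResult:
    """WT/mutant fold change with an unpaired Student's t test.

    ``unit='day'`` (default) tests day-level means, treating technical
    replicates as pseudo-replication; ``unit='well'`` tests raw well ratios.
    """
    if unit not in ("day", "well"):
        raise ValueError("unit must be 'day' or 'well'")
    if unit == "day":
        wt = day_means(wells, "WT")
        mut = day_means(wells, "mutant")
    else:
        wt = [w.ratio for w in wells if w.construct == "WT"]
        mut = [w.ratio for w in wells if w.construct == "mutant"]
    if not wt or not mut:
        raise ValueError("both WT and mutant wells are required")
    fold = float(np.mean(wt)) / float(np.mean(mut))
    n_days = len({w.day for w in wells if w.construct == "WT"})
    if len(wt) < 2 or len(mut) < 2:
        return ReporterResult(fold, math.nan, "ns", n_days)
    if np.var(wt) == 0 and np.var(mut) == 0:
        # degenerate: no variance at all; identical means are a certain null
        p = 1.0 if np.mean(wt) == np.mean(mut) else 0.0
    else:
        p = float(stats.ttest_ind(wt, mut, equal_var=True).pvalue)
    return ReporterResult(fold, p, significance_stars(p), n_days)


def qpcr_fold(records: list[QpcrRecord], mode: str = "ct_ratio") -> float:
    """mRNA-level WT/mutant ratio from qPCR threshold cycles.

    mode='ct_ratio' (default): per construct, mean CT(Rluc)/mean CT(Fluc);
    result is the WT ratio divided by the mutant ratio.  mode='ddct':
    conventional 2^-(dCt_WT - dCt_mutant) with dCt = CT(Rluc) - CT(Fluc).
    """
    if mode not in ("ct_ratio", "ddct"):
        raise ValueError("mode must be 'ct_ratio' or 'ddct'")
    means: dict[tuple[str, str], float] = {}
    for construct in ("WT", "mutant"):
        for target in ("Rluc", "Fluc"):
            cts = [r.ct for r in records if r.construct == construct and r.target == target]
            if not cts:
                raise ValueError(f"no CT values for {construct}/{target}")
            means[(construct, target)] = float(np.mean(cts))
    if mode == "ct_ratio":
        wt = means[("WT", "Rluc")] / means[("WT", "Fluc")]
        mut = means[("mutant", "Rluc")] / means[("mutant", "Fluc")]
        return wt / mut
    dct_wt = means[("WT", "Rluc")] - means[("WT", "Fluc")]
    dct_mut = means[("mutant", "Rluc")] - means[("mutant", "Fluc")]
    return float(2.0 ** -(dct_wt - dct_mut))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_wells(path: str | Path) -> list[LuciferaseWell]:
    """CSV columns: construct,day,tech_rep,rluc,fluc."""
    wells = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            wells.append(
                LuciferaseWell(
                    construct=row["construct"],
                    day=int(row["day"]),
                    tech_rep=int(row["tech_rep"]),
                    rluc=float(row["rluc"]),
                    fluc=float(row["fluc"]),
                )
            )
    if not wells:
        raise ValueError(f"no wells in {path}")
    return wells


def read_qpcr(path: str | Path) -> list[QpcrRecord]:
    """CSV columns: target,construct,replicate,ct."""
    records = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            records.append(
                QpcrRecord(
                    target=row["target"],
                    construct=row["construct"],
                    replicate=int(row["replicate"]),
                    ct=float(row["ct"]),
                )
            )
    if not records:
        raise ValueError(f"no qPCR records in {path}")
    return records


def write_wells(wells: list[LuciferaseWell], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["construct", "day", "tech_rep", "rluc", "fluc"])
        for w in wells:
            writer.writerow(
                [w.construct, w.day, w.tech_rep, repr(float(w.rluc)), repr(float(w.fluc))]
            )
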