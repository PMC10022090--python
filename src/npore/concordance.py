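"""Read concordance measured as per-position Gini purity.

For a pileup column with class counts c_1..c_N (classes A, C, G, T and
deletion), the Gini purity is ``GP = sum_i (c_i / total)^2``: 1 when all
reads agree, 1/N for an even split over N classes. Insertions are scored
separately per reference junction k -> k+1, the classes being every distinct
inserted string including the empty insertion; they get their own histogram
because the variable class count shifts the GP distribution. Low-purity
columns are where reads disagree and variant callers struggle, so a
realignment that increases purity makes downstream pileup-based calling
easier.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pysam

DEFAULT_MIN_DEPTH = 5
DEFAULT_BIN_WIDTH = 0.01


def gini_purity(counts: Iterable[int]) -> float:
    """``sum((c / total)^2)`` over class counts; total must be positive."""
    arr = np.asarray(list(counts), dtype=float)
    if (arr < 0).any():
        raise ValueError("negative class count")
    total = arr.sum()
    if total <= 0:
        raise ValueError("column has zero total count; skip instead of scoring")
    p = arr / total
    return float(np.dot(p, p))


@dataclass
class GiniHistogram:
    """Binned GP counts for pileup columns and for insertion junctions."""

    bin_width: float
    columns: np.ndarray    # count of scored columns per GP bin
    insertions: np.ndarray

    @property
    def edges(self) -> np.ndarray:
        nb = len(self.columns)
        return np.linspace(0.0, 1.0, nb + 1)

    def fraction_below(self, threshold: float, which: str = "columns") -> float:
        hist = self.columns if which == "columns" else self.insertions
        total = hist.sum()
        if total == 0:
            return 0.0
        edges = self.edges
        mask = edges[1:] <= threshold + 1e-12
        return float(hist[mask].sum() / total)

    def to_tsv(self, path: str) -> None:
        edges = self.edges
        with open(path, "w") as fh:
            fh.write("bin_low\tbin_high\tcolumn_count\tinsertion_count\n")
            for k in range(len(self.columns)):
                fh.write(f"{edges[k]:.4f}\t{edges[k + 1]:.4f}\t"
                         f"{int(self.columns[k])}\t{int(self.insertions[k])}\n")


def _bin(hist: np.ndarray, gp: float) -> None:
    nb = len(hist)
    k = min(nb - 1, int(gp / (1.0 / nb)))
    hist[k] += 1


def column_counts(pileup_column) -> Counter:
    """A/C/G/T/deletion counts for one pysam pileup column."""
    counts: Counter = Counter()
    for pr in pileup_column.pileups:
        if pr.is_refskip:
            continue
        if pr.is_del:
            counts["-"] += 1
        elif pr.query_position is not None:
            base = pr.alignment.query_sequence[pr.query_position].upper()
            if base in "ACGT":
                counts[base] += 1
    return counts


def insertion_counts(pileup_column) -> Counter:
    """Insertion-string counts (epsilon included) at the junction after
    this column's reference position."""
    counts: Counter = Counter()
    for pr in pileup_column.pileups:
        if pr.is_refskip or pr.is_del:
            continue
        if pr.query_position is None:
            continue
        g = pr.indel
        if g > 0:
            qpos = pr.query_position
            counts[pr.alignment.query_sequence[qpos + 1:qpos + 1 + g]] += 1
        else:
            counts[""] += 1
    return counts


def gini_histograms(bam_path: str, ref_path: str | None = None,
                    bin_width: float = DEFAULT_BIN_WIDTH,
                    min_depth: int = DEFAULT_MIN_DEPTH,
                    by_haplotype: bool = False,
                    region: str | None = None) -> GiniHistogram:
    """Score every sufficiently covered pileup column of an indexed BAM.

    ``by_haplotype`` groups reads by their HP tag before scoring (untagged
    reads form an "unphased" group, with a warning if the tag is absent
    altogether); each group's columns are scored independently.
    """
    nb = int(round(1.0 / bin_width))
    col_hist = np.zeros(nb, dtype=np.int64)
    ins_hist = np.zeros(nb, dtype=np.int64)

    with pysam.AlignmentFile(bam_path) as bam:
        if by_haplotype:
            groups = _haplotype_groups(bam)
        else:
            groups = {None: None}
        for hap, names in groups.items():
            with pysam.AlignmentFile(bam_path) as fh:
                for col in fh.pileup(region=region, truncate=True,
                                     min_base_quality=0):
                    if names is not None:
                        col_counts, ins_counts = _filtered_counts(col, names)
                    else:
                        col_counts = column_counts(col)
                        ins_counts = insertion_counts(col)
                    if sum(col_counts.values()) >= min_depth:
                        _bin(col_hist, gini_purity(col_counts.values()))
                    if sum(ins_counts.values()) >= min_depth:
                        _bin(ins_hist, gini_purity(ins_counts.values()))
    return GiniHistogram(bin_width=bin_width, columns=col_hist,
                         insertions=ins_hist)


def _haplotype_groups(bam) -> dict:
    import warnings

    groups: dict = {}
    tagged = False
    for read in bam.fetch():
        hp = read.get_tag("HP") if read.has_tag("HP") else None
        tagged = tagged or hp is not None
        groups.setdefault(hp, set()).add(read.query_name)
    if not tagged:
        warnings.warn("no HP tags found; scoring all reads as one unphased group")
    return groups


def _filtered_counts(col, names) -> tuple[Counter, Counter]:
    cc: Counter = Counter()
    ic: Counter = Counter()
    for pr in col.pileups:
        if pr.alignment.query_name not in names or pr.is_refskip:
            continue
        if pr.is_del:
            cc["-"] += 1
            continue
        if pr.query_position is None:
            continue
        base = pr.alignment.query_sequence[pr.query_position].upper()
        if base in "ACGT":
            cc[base] += 1
        g = pr.indel
        if g > 0:
            qpos = pr.query_position
            ic[pr.alignment.query_sequence[qpos + 1:qpos + 1 + g]] += 1
        else:
            ic[""] += 1
    return cc, ic
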