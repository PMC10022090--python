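"""Reference n-polymer annotation.

An *n-polymer* is a run of at least three exact copies of the same 1-6 bp
repeat unit: homopolymers (n=1) such as ``AAAAA`` and short tandem repeats
(2 <= n <= 6) such as ``ACACACAC``. For every repeat-unit length ``n`` each
reference position that starts a repeat unit is annotated with

* ``l``   -- the total number of consecutive unit copies in the polymer, and
* ``idx`` -- the 0-based index of that unit within the polymer.

Positions that do not start a unit of an eligible polymer carry ``l = 0``.
Phase-shifted polymers of the same ``n`` overlap and are each annotated
(``ATATATAT`` holds both AT x 4 and TA x 3); polymers of different ``n`` may
overlap freely. ``N`` bases never match anything, including themselves, and
therefore break repeats.

These annotations gate the repeat shortening/lengthening transitions of the
aligner: a copy-number indel may only start at a polymer start (``l > 0`` and
``idx == 0``) and continue across subsequent unit starts (``l > 0``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class AnnotationParams:
    """Parameters of the n-polymer definition.

    n_max : largest repeat-unit length considered (units of 1..n_max bp).
    min_repeats : minimum number of exact unit copies (3 by definition;
        with only 2 copies no unit is bordered on both sides by another
        copy, so basecalling errors there are rare).
    l_max : size of the copy-count axis of the score tensor; true copy
        counts are stored as-is but clamped to ``l_max - 1`` when used as
        tensor indices.
    """

    n_max: int = 6
    min_repeats: int = 3
    l_max: int = 100

    def __post_init__(self) -> None:
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.min_repeats < 3:
            raise ValueError("min_repeats must be >= 3 (n-polymer definition)")
        if self.l_max < self.min_repeats:
            raise ValueError("l_max must be >= min_repeats")


@dataclass
class NPolymerAnnotation:
    """Per-n, per-position repeat annotation of one reference sequence."""

    params: AnnotationParams
    length: int
    #: ``l[n - 1][p]`` = copy count of the polymer whose unit starts at p (0 if none)
    l: list[np.ndarray] = field(repr=False)
    #: ``idx[n - 1][p]`` = 0-based unit index within that polymer
    idx: list[np.ndarray] = field(repr=False)

    def l_of(self, n: int, pos: int) -> int:
        return int(self.l[n - 1][pos])

    def idx_of(self, n: int, pos: int) -> int:
        return int(self.idx[n - 1][pos])

    def anchors(self, n: int):
        """Yield ``(start, copies)`` for every polymer of unit length n."""
        ln = self.l[n - 1]
        ix = self.idx[n - 1]
        for p in np.flatnonzero((ln > 0) & (ix == 0)):
            yield int(p), int(ln[p])

    def nonzero_by_column(self) -> list[list[tuple[int, int, int]]]:
        """Per-position list of ``(n, l, idx)`` for annotated unit starts.

        Dense helper for the aligner's inner loop: most positions carry no
        annotation, so the per-column lists are almost always empty.
        """
        cols: list[list[tuple[int, int, int]]] = [[] for _ in range(self.length)]
        for n in range(1, self.params.n_max + 1):
            ln = self.l[n - 1]
            ix = self.idx[n - 1]
            for p in np.flatnonzero(ln > 0):
                cols[p].append((n, int(ln[p]), int(ix[p])))
        return cols


def annotate_reference(seq: str, params: AnnotationParams | None = None) -> NPolymerAnnotation:
    """Annotate every eligible n-polymer unit start of ``seq``.

    For each unit length ``n`` the sequence is scanned for maximal stretches
    with period ``n`` (``seq[q] == seq[q + n]``); within such a stretch each
    of the ``n`` phase classes forms a candidate polymer whose copy count is
    the number of whole units that fit, and polymers with at least
    ``min_repeats`` copies are annotated at every unit start. Runs in
    O(|seq| * n_max) time and stores O(|seq| * n_max) integers.
    """
    params = params or AnnotationParams()
    for p, ch in enumerate(seq):
        if ch not in _VALID:
            raise ValueError(f"invalid base {ch!r} at position {p}")
    L = len(seq)
    l_arrs = [np.zeros(L, dtype=np.int32) for _ in range(params.n_max)]
    idx_arrs = [np.zeros(L, dtype=np.int32) for _ in range(params.n_max)]
    if L == 0:
        return NPolymerAnnotation(params, 0, l_arrs, idx_arrs)

    for n in range(1, params.n_max + 1):
        ln = l_arrs[n - 1]
        ixn = idx_arrs[n - 1]
        # periodic[q] <=> seq[q] == seq[q+n], with N equal to nothing
        s = 0
        while s < L - n:
            if seq[s] != seq[s + n] or seq[s] == "N":
                s += 1
                continue
            t = s
            while t < L - n and seq[t] == seq[t + n] and seq[t] != "N":
                t += 1
            region_len = (t - s) + n  # [s, t + n) has period n throughout
            for r in range(n):
                copies = (region_len - r) // n
                if copies >= params.min_repeats:
                    for k in range(copies):
                        p = s + r + k * n
                        ln[p] = copies
                        ixn[p] = k
            # periodic[t] is False (or t hit the tail), so the next maximal
            # periodic stretch can begin no earlier than t + 1
            s = t + 1
    return NPolymerAnnotation(params, L, l_arrs, idx_arrs)


# ---------------------------------------------------------------------------
# stratification BEDs

def polymer_intervals(ann: NPolymerAnnotation, n: int, slop: int = 1) -> list[tuple[int, int]]:
    """Half-open intervals covering every n-polymer, widened by ``slop`` bp."""
    iv = []
    for start, copies in ann.anchors(n):
        iv.append((max(0, start - slop), min(ann.length, start + n * copies + slop)))
    return merge_intervals(iv)


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def complement_intervals(intervals: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    out = []
    prev = 0
    for s, e in intervals:
        if s > prev:
            out.append((prev, s))
        prev = max(prev, e)
    if prev < length:
        out.append((prev, length))
    return out


def write_stratification_beds(ann: NPolymerAnnotation, contig: str, out_prefix: str,
                              slop: int = 1) -> dict[str, str]:
    """Write per-n, merged all-n, and complement BED files.

    Returns a mapping from stratum name to written path.
    """
    paths = {}
    all_iv: list[tuple[int, int]] = []
    for n in range(1, ann.params.n_max + 1):
        iv = polymer_intervals(ann, n, slop=slop)
        all_iv.extend(iv)
        path = f"{out_prefix}.np{n}.bed"
        _write_bed(path, contig, iv)
        paths[f"np{n}"] = path
    merged = merge_intervals(all_iv)
    _write_bed(f"{out_prefix}.np_all.bed", contig, merged)
    paths["np_all"] = f"{out_prefix}.np_all.bed"
    comp = complement_intervals(merged, ann.length)
    _write_bed(f"{out_prefix}.np_none.bed", contig, comp)
    paths["np_none"] = f"{out_prefix}.np_none.bed"
    return paths


def _write_bed(path: str, contig: str, intervals: list[tuple[int, int]]) -> None:
    with open(path, "w") as fh:
        for s, e in intervals:
            fh.write(f"{contig}\t{s}\t{e}\n")
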