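"""Follow-banding: restrict the DP to a band around the original alignment.

A mapped read's existing CIGAR is a good guess at the new optimal path, so
instead of filling the full |read| x |window| matrix the DP is evaluated in a
band of half-width ``b`` that follows that path. Every M op is first expanded
to I-then-D so the path moves one matrix row or column per step; computation
then proceeds one anti-diagonal of width 2b+1 at a time, shifting right or
down according to the expanded op. A cell of the compact (2b+1) x (path
length) matrix B at (offset j, step i) corresponds to full-matrix coordinates
``row = INSs[i] + b - j``, ``col = DELs[i] - b + j``, where INSs/DELs are the
cumulative I/D counts along the expanded path. Memory is O(b * path length)
instead of O(|read| * |window|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import _engine
from .align import AlignmentResult, BandTooNarrowError, _columns
from .annotation import NPolymerAnnotation
from .cigar import collapse_cigar, parse_cigar
from .model import PenaltyModel

DEFAULT_BAND = 30


def expand_to_id(cigar: str) -> str:
    """Expand a CIGAR over {M, I, D} to the op-per-base {I, D} path.

    Each M becomes I-then-D (one read base, then one reference base); I and D
    pass through. ``"2M" -> "IDID"``. The result has one op per consumed base.
    """
    parts = []
    for count, op in parse_cigar(cigar):
        if op == "M":
            parts.append("ID" * count)
        elif op == "I":
            parts.append("I" * count)
        elif op == "D":
            parts.append("D" * count)
        else:
            raise ValueError(f"expand_to_id requires M/I/D CIGARs, got {op!r}")
    return "".join(parts)


def band_coords(i: int, j: int, inss, dels, b: int):
    """Full-matrix ``(row, col)`` of banded cell (step i, offset j).

    Returns ``(row, col, in_bounds)``; out-of-bounds cells are a valid,
    flagged result (they are simply never computed).
    """
    if not 0 <= j <= 2 * b:
        raise ValueError("offset outside the band")
    row = inss[i] + b - j
    col = dels[i] - b + j
    in_bounds = 0 <= row <= inss[-1] and 0 <= col <= dels[-1]
    return row, col, in_bounds


@dataclass
class BandedWorkspace:
    """Precomputed band geometry for one read's realignment."""

    b: int
    id_path: str
    inss: list[int] = field(repr=False)
    dels: list[int] = field(repr=False)

    @classmethod
    def from_cigar(cls, cigar: str, b: int = DEFAULT_BAND) -> "BandedWorkspace":
        path = expand_to_id(cigar)
        inss = [0] * (len(path) + 1)
        dels = [0] * (len(path) + 1)
        for d, op in enumerate(path):
            ins = op == "I"
            inss[d + 1] = inss[d] + ins
            dels[d + 1] = dels[d] + (not ins)
        return cls(b=b, id_path=path, inss=inss, dels=dels)

    @property
    def cell_count(self) -> int:
        """Cells allocated per matrix: (2b+1) x (|read| + window + 1)."""
        return (2 * self.b + 1) * (len(self.id_path) + 1)

    def coords(self, i: int, j: int):
        return band_coords(i, j, self.inss, self.dels, self.b)


def banded_align(read: str, ref_window: str, original_cigar: str,
                 model: PenaltyModel,
                 annotation: NPolymerAnnotation | None = None,
                 b: int = DEFAULT_BAND,
                 workspace: BandedWorkspace | None = None,
                 read_id: str | None = None, ref_start: int = 0) -> AlignmentResult:
    """Repeat-aware realignment restricted to a follow-band.

    Identical contract to :func:`npore.align.align` but cells farther than
    ``b`` from the original alignment path are treated as +inf; raises
    :class:`BandTooNarrowError` if the terminal cell becomes unreachable.
    Copy-number transitions whose forward-write target falls outside the band
    are dropped, never written out of bounds.
    """
    _engine.validate_seed(original_cigar, read, ref_window)
    ws = workspace or BandedWorkspace.from_cigar(original_cigar, b)
    ann_cols = _columns(ref_window, model, annotation)
    raw, score, cells = _engine.run_banded(read, ref_window, ws.inss, ws.b,
                                           model, ann_cols)
    assert cells == ws.cell_count
    return AlignmentResult(cigar=collapse_cigar(raw), score=score,
                           ref_start=ref_start,
                           ref_end=ref_start + len(ref_window), read_id=read_id)


__all__ = [
    "DEFAULT_BAND", "BandTooNarrowError", "BandedWorkspace", "band_coords",
    "banded_align", "expand_to_id",
]
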