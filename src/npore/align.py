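"""Repeat-aware global alignment of a read against a reference window."""

from __future__ import annotations

from dataclasses import dataclass

from . import _engine
from .annotation import NPolymerAnnotation, annotate_reference
from .cigar import collapse_cigar, consumed
from .model import PenaltyModel

BandTooNarrowError = _engine.BandTooNarrowError


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment: collapsed CIGAR over {M, I, D} plus its penalty."""

    cigar: str
    score: float
    ref_start: int = 0
    ref_end: int = 0
    read_id: str | None = None

    def __post_init__(self) -> None:
        nread, nref = consumed(self.cigar)
        if self.ref_end - self.ref_start != nref:
            raise ValueError("CIGAR reference span inconsistent with window")


def align(read: str, ref_window: str, model: PenaltyModel,
          annotation: NPolymerAnnotation | None = None,
          read_id: str | None = None, ref_start: int = 0) -> AlignmentResult:
    """Unbanded global alignment of ``read`` to ``ref_window``.

    ``annotation`` must annotate ``ref_window`` itself; when omitted it is
    computed on the fly (and skipped entirely if the model carries no
    copy-number tensor). Runs the banded engine with a band wide enough to
    cover the whole matrix.
    """
    ann_cols = _columns(ref_window, model, annotation)
    seed = _seed_cigar(len(read), len(ref_window))
    inss = _engine.inss_from_cigar(seed) if seed else [0]
    b = max(len(read), 1)
    raw, score, _ = _engine.run_banded(read, ref_window, inss, b, model, ann_cols)
    return AlignmentResult(cigar=collapse_cigar(raw), score=score,
                           ref_start=ref_start,
                           ref_end=ref_start + len(ref_window), read_id=read_id)


def score_cigar(read: str, ref_window: str, cigar: str, model: PenaltyModel,
                annotation: NPolymerAnnotation | None = None) -> float:
    """Minimum model penalty of the exact alignment path a CIGAR encodes.

    Replays the dynamic program restricted to the path itself (band of
    half-width 0), so gap runs are charged as affine gaps or copy-number
    events, whichever legal interpretation is cheaper.
    """
    _engine.validate_seed(cigar, read, ref_window)
    ann_cols = _columns(ref_window, model, annotation)
    inss = _engine.inss_from_cigar(cigar)
    _, score, _ = _engine.run_banded(read, ref_window, inss, 0, model, ann_cols)
    return score


def _columns(ref_window: str, model: PenaltyModel,
             annotation: NPolymerAnnotation | None):
    if not model.npoly_enabled:
        return None
    if annotation is None:
        annotation = annotate_reference(ref_window, model.annotation_params())
    if annotation.length != len(ref_window):
        raise ValueError("annotation does not correspond to ref_window")
    return annotation.nonzero_by_column()


def _seed_cigar(nread: int, nref: int) -> str:
    k = min(nread, nref)
    parts = []
    if k:
        parts.append(f"{k}M")
    if nread > k:
        parts.append(f"{nread - k}I")
    if nref > k:
        parts.append(f"{nref - k}D")
    return "".join(parts)
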