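"""Alignment penalty estimation and storage.

Every penalty is the negative natural log of a measured event frequency, so
minimising total alignment penalty is equivalent to maximising the joint
likelihood of the implied errors/mutations (assuming independence):

* ``P``                 -- 4x4 substitution penalties,
                           ``P[i, j] = -log((C_P[i, j] + eps) / (sum(C_P[i, :]) + eps))``
* ``G_open, G_extend``  -- affine gap parameters fit to the per-length indel
                           penalty curve (defaults 5 and 1)
* ``N``                 -- n_max x l_max x l_max copy-number penalty tensor:
                           ``N[n, i, j]`` is the cost of observing ``j`` copies
                           of an n-bp repeat unit where the reference has ``i``.

``eps`` (default 0.01) keeps the logs finite when events were never observed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .annotation import AnnotationParams, NPolymerAnnotation
from .cigar import parse_cigar

BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(BASES)}

DEFAULT_EPS = 0.01
DEFAULT_G_OPEN = 5.0
DEFAULT_G_EXTEND = 1.0
MAX_INDEL_LEN = 50  # length bucket cap for C_I / C_D


# ---------------------------------------------------------------------------
# confusion counting

@dataclass
class ConfusionCounts:
    """Raw confusion statistics gathered from alignments.

    ``C_P[i, j]`` counts reference base i aligned to read base j.
    ``C_I[g]`` / ``C_D[g]`` count contiguous insertion/deletion runs of length
    g (bucket 0 counts aligned columns carrying no such event, so that
    normalised frequencies are per-opportunity probabilities).
    ``C_N[n-1, i, j]`` counts reference n-polymers with i expected and j
    observed unit copies among reads that span the polymer end-to-end.
    """

    n_max: int = 6
    l_max: int = 100
    C_P: np.ndarray = field(default=None)  # type: ignore[assignment]
    C_I: np.ndarray = field(default=None)  # type: ignore[assignment]
    C_D: np.ndarray = field(default=None)  # type: ignore[assignment]
    C_N: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.C_P is None:
            self.C_P = np.zeros((4, 4), dtype=np.int64)
        if self.C_I is None:
            self.C_I = np.zeros(MAX_INDEL_LEN + 1, dtype=np.int64)
        if self.C_D is None:
            self.C_D = np.zeros(MAX_INDEL_LEN + 1, dtype=np.int64)
        if self.C_N is None:
            self.C_N = np.zeros((self.n_max, self.l_max, self.l_max), dtype=np.int64)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        if (self.n_max, self.l_max) != (other.n_max, other.l_max):
            raise ValueError("incompatible count shapes")
        return ConfusionCounts(
            self.n_max, self.l_max,
            self.C_P + other.C_P, self.C_I + other.C_I,
            self.C_D + other.C_D, self.C_N + other.C_N,
        )


def count_confusions(alignments, annotation: NPolymerAnnotation,
                     counts: ConfusionCounts | None = None) -> ConfusionCounts:
    """Accumulate confusion counts from ``(read, ref_window, cigar[, ref_start])``.

    ``annotation`` must annotate the reference the windows were cut from;
    ``ref_start`` (default 0) locates each window on that reference. Aligned
    base pairs feed ``C_P``; each contiguous insertion/deletion run feeds one
    ``C_I``/``C_D`` bucket at its run length; every annotated polymer spanned
    end-to-end (with 1 bp flanks) by the read feeds ``C_N`` at (n, expected
    copies, observed copies), where observed = expected + net inserted bases
    within the span / n, counted only when the net is a whole number of units.
    """
    cc = counts if counts is not None else ConfusionCounts(
        annotation.params.n_max, annotation.params.l_max)
    for item in alignments:
        read, refw, cig, *rest = item
        ref_start = rest[0] if rest else 0
        _count_one(cc, read, refw, cig, ref_start, annotation)
    return cc


def _count_one(cc: ConfusionCounts, read: str, refw: str, cig: str,
               ref_start: int, ann: NPolymerAnnotation) -> None:
    ops = parse_cigar(cig)
    nread = sum(c for c, o in ops if o in "MIS=X")
    nref = sum(c for c, o in ops if o in "MDN=X")
    if nread != len(read) or nref != len(refw):
        raise ValueError(
            f"CIGAR {cig!r} inconsistent with read({len(read)})/ref({len(refw)}) lengths")

    i = j = 0  # read, window cursors
    aligned_cols = 0
    n_ins_runs = n_del_runs = 0
    del_pos: set[int] = set()          # window-relative deleted ref positions
    ins_at: dict[int, int] = {}        # junction k (after window base k) -> ins len
    for count, op in ops:
        if op in "M=X":
            for t in range(count):
                rb, qb = refw[j + t], read[i + t]
                if rb in _B2I and qb in _B2I:
                    cc.C_P[_B2I[rb], _B2I[qb]] += 1
            aligned_cols += count
            i += count
            j += count
        elif op == "I":
            cc.C_I[min(count, MAX_INDEL_LEN)] += 1
            n_ins_runs += 1
            ins_at[j - 1] = ins_at.get(j - 1, 0) + count
            i += count
        elif op == "D":
            cc.C_D[min(count, MAX_INDEL_LEN)] += 1
            n_del_runs += 1
            del_pos.update(range(j, j + count))
            j += count
        elif op in "SH":
            if op == "S":
                i += count
        else:
            raise ValueError(f"unsupported CIGAR op {op!r}")
    cc.C_I[0] += max(0, aligned_cols - n_ins_runs)
    cc.C_D[0] += max(0, aligned_cols - n_del_runs)

    # n-polymer copy-number observations
    w_lo, w_hi = ref_start, ref_start + len(refw)
    for n in range(1, cc.n_max + 1):
        for start, copies in ann.anchors(n):
            span_lo, span_hi = start, start + n * copies
            if span_lo - 1 < w_lo or span_hi + 1 > w_hi:
                continue  # read must span the polymer with 1 bp flanks
            a, b = span_lo - ref_start, span_hi - ref_start
            ndel = sum(1 for p in range(a, b) if p in del_pos)
            nins = sum(g for k, g in ins_at.items() if a - 1 <= k <= b - 1)
            net = nins - ndel
            if net % n != 0:
                continue
            obs = copies + net // n
            if obs < 0:
                continue
            ei = min(copies, cc.l_max - 1)
            oj = min(obs, cc.l_max - 1)
            cc.C_N[n - 1, ei, oj] += 1


# ---------------------------------------------------------------------------
# penalties from counts

def substitution_penalties(C_P: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Row-normalised negative log frequencies of base confusions."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    C = np.asarray(C_P, dtype=float)
    return -np.log((C + eps) / (C.sum(axis=1, keepdims=True) + eps))


def indel_penalty_curve(C: np.ndarray, eps: float = DEFAULT_EPS) -> dict[int, float]:
    """Per-length gap penalties ``-log((C[g] + eps) / (sum(C) + eps))``.

    Returns a dict over observed lengths g >= 1 (lengths never seen are
    omitted; bucket 0, the no-event count, contributes to the denominator
    only).
    """
    C = np.asarray(C, dtype=float)
    tot = C.sum()
    return {g: float(-np.log((C[g] + eps) / (tot + eps)))
            for g in range(1, len(C)) if C[g] > 0}


def fit_affine(penalties: dict[int, float]) -> tuple[float, float]:
    """Least-squares fit ``penalty(g) ~ G_open + (g - 1) * G_extend``.

    Falls back to the defaults (5, 1) with a warning when fewer than two gap
    lengths were observed. Both parameters are clipped at 0.
    """
    if len(penalties) < 2:
        warnings.warn("fewer than 2 observed gap lengths; using default affine "
                      f"parameters ({DEFAULT_G_OPEN}, {DEFAULT_G_EXTEND})")
        return DEFAULT_G_OPEN, DEFAULT_G_EXTEND
    gs = np.array(sorted(penalties))
    ys = np.array([penalties[g] for g in gs])
    g_ext, g_open = np.polyfit(gs - 1, ys, 1)
    return float(max(0.0, g_open)), float(max(0.0, g_ext))


def npolymer_penalties(C_N: np.ndarray, eps: float = DEFAULT_EPS,
                       regularize: bool = True,
                       printed_direction: bool = False) -> np.ndarray:
    """Copy-number penalty tensor from polymer confusion counts.

    Each expected-length row is normalised independently:
    ``N[n, i, j] = -log((C_N[n, i, j] + eps) / (sum_j C_N[n, i, :] + eps))``.

    With ``regularize`` two monotonicity families are then enforced for all
    in-bounds offsets k > 0 (default semantics: the more likely event gets
    the lower penalty):

    1. shorter indels are more likely:   ``N[n, i, i±k] < N[n, i, i±(k+1)]``
    2. longer polymers are more likely to contain an indel of a given size:
       ``N[n, i+1, (i+1)±k] < N[n, i, i±k]``

    ``printed_direction=True`` flips both inequalities.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    C = np.asarray(C_N, dtype=float)
    N = -np.log((C + eps) / (C.sum(axis=2, keepdims=True) + eps))
    if regularize:
        N = regularize_npolymer(N, printed_direction=printed_direction)
    return N


def regularize_npolymer(N: np.ndarray, delta: float = 1e-6,
                        printed_direction: bool = False) -> np.ndarray:
    """Enforce the two monotonicity families by minimal upward adjustment.

    Constraints form a DAG over (expected length i, offset k), so one
    relaxation pass in topological order (i away from the constraint source,
    k outward) reaches the fixed point that repeated monotone sweeps converge
    to; every adjusted entry is raised to the binding bound plus ``delta``.
    """
    N = np.array(N, dtype=float, copy=True)
    n_dims, l_max, _ = N.shape
    # Default (prose) semantics raise row i above row i+1 and larger offsets
    # above smaller ones; the printed direction flips both, so rows are
    # processed in the opposite order and offsets walked inward.
    if not printed_direction:
        i_order = range(l_max - 1, -1, -1)
    else:
        i_order = range(l_max)
    for nn in range(n_dims):
        for i in i_order:
            other = i + 1 if not printed_direction else i - 1
            for sign in (1, -1):
                # family 2: row `i` must exceed the already-final row `other`
                # (the boundary row has no source and gets family 1 only)
                for k in range(1, l_max):
                    j = i + sign * k
                    jo = other + sign * k
                    if not 0 <= j < l_max:
                        break
                    if (0 <= other < l_max and 0 <= jo < l_max
                            and N[nn, i, j] < N[nn, other, jo] + delta):
                        N[nn, i, j] = N[nn, other, jo] + delta
                # family 1 within the row
                if not printed_direction:
                    for k in range(2, l_max):  # raise larger offsets
                        j = i + sign * k
                        if not 0 <= j < l_max:
                            break
                        prev = N[nn, i, i + sign * (k - 1)]
                        if N[nn, i, j] < prev + delta:
                            N[nn, i, j] = prev + delta
                else:
                    ks = [k for k in range(1, l_max) if 0 <= i + sign * k < l_max]
                    for k in reversed(ks[:-1]):  # raise smaller offsets
                        outer = N[nn, i, i + sign * (k + 1)]
                        if N[nn, i, i + sign * k] < outer + delta:
                            N[nn, i, i + sign * k] = outer + delta
    return N


# ---------------------------------------------------------------------------
# the model

@dataclass
class PenaltyModel:
    """All penalties used by the aligner.

    ``N=None`` disables the repeat shortening/lengthening transitions, which
    reduces the aligner to plain affine-gap (Gotoh) global alignment.
    """

    P: np.ndarray
    G_open: float = DEFAULT_G_OPEN
    G_extend: float = DEFAULT_G_EXTEND
    N: np.ndarray | None = None
    eps: float = DEFAULT_EPS
    n_max: int = 6
    l_max: int = 100

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (4, 4):
            raise ValueError("P must be 4x4")
        if self.N is not None:
            self.N = np.asarray(self.N, dtype=float)
            if self.N.shape != (self.n_max, self.l_max, self.l_max):
                raise ValueError("N must be n_max x l_max x l_max")
        self._P_list = self.P.tolist()
        self._N_list = self.N.tolist() if self.N is not None else None
        # non-ACGT bases score as the worst substitution and are never
        # eligible for repeat transitions
        self._max_sub = float(self.P.max())

    @property
    def npoly_enabled(self) -> bool:
        return self.N is not None

    def sub_cost(self, ref_base: str, read_base: str) -> float:
        i = _B2I.get(ref_base)
        j = _B2I.get(read_base)
        if i is None or j is None:
            return self._max_sub
        return self._P_list[i][j]

    def gap_cost(self, length: int) -> float:
        """Affine cost of a gap run: ``G_open + (length - 1) * G_extend``."""
        if length < 1:
            raise ValueError("gap length must be >= 1")
        return self.G_open + (length - 1) * self.G_extend

    def n_cost(self, n: int, expected: int, observed: int) -> float:
        """Copy-number penalty with indices clamped to the tensor bounds."""
        if self.N is None:
            raise ValueError("model has no n-polymer tensor")
        i = min(expected, self.l_max - 1)
        j = min(max(observed, 0), self.l_max - 1)
        return self._N_list[n - 1][i][j]

    def annotation_params(self) -> AnnotationParams:
        return AnnotationParams(n_max=self.n_max, l_max=self.l_max)

    # -- constructors -------------------------------------------------------

    @classmethod
    def affine_only(cls, G_open: float = DEFAULT_G_OPEN,
                    G_extend: float = DEFAULT_G_EXTEND,
                    match_cost: float = 0.0, mismatch_cost: float = 4.0) -> "PenaltyModel":
        """Plain affine-gap model (no repeat transitions)."""
        P = np.full((4, 4), mismatch_cost, dtype=float)
        np.fill_diagonal(P, match_cost)
        return cls(P=P, G_open=G_open, G_extend=G_extend, N=None)

    @classmethod
    def from_counts(cls, counts: ConfusionCounts, eps: float = DEFAULT_EPS,
                    printed_direction: bool = False) -> "PenaltyModel":
        """Estimate all penalties from measured confusion statistics."""
        P = substitution_penalties(counts.C_P, eps)
        curve_i = indel_penalty_curve(counts.C_I, eps)
        curve_d = indel_penalty_curve(counts.C_D, eps)
        curve = {g: min(curve_i.get(g, np.inf), curve_d.get(g, np.inf))
                 for g in set(curve_i) | set(curve_d)}
        g_open, g_ext = fit_affine(curve)
        N = npolymer_penalties(counts.C_N, eps, printed_direction=printed_direction)
        return cls(P=P, G_open=g_open, G_extend=g_ext, N=N, eps=eps,
                   n_max=counts.n_max, l_max=counts.l_max)

    @classmethod
    def default(cls, n_max: int = 6, l_max: int = 100) -> "PenaltyModel":
        """Parametric nanopore-flavoured default model.

        Substitutions assume a uniform ~1.5% error rate. The copy-number
        tensor is derived from a simple parametric error family in which the
        per-polymer indel probability grows with polymer length and shrinks
        with repeat-unit size (roughly matching R9.4.1 behaviour, where a
        10 bp homopolymer miscalls its length ~40% of the time), error
        magnitudes are geometric, and lengthenings are slightly more common
        than shortenings. The same probability family drives the read
        simulator's default error process, so models trained on simulated
        data should recover this tensor.
        """
        P = np.full((4, 4), -np.log(0.005))
        np.fill_diagonal(P, -np.log(0.985))
        probs = copy_number_confusion_probs(n_max, l_max)
        with np.errstate(divide="ignore"):
            N = -np.log(probs)
        N = np.minimum(N, 50.0)
        N = regularize_npolymer(N)
        return cls(P=P, G_open=DEFAULT_G_OPEN, G_extend=DEFAULT_G_EXTEND, N=N,
                   n_max=n_max, l_max=l_max)

    # -- serialization ------------------------------------------------------

    def save(self, path: str) -> None:
        obj = {
            "format": "npore-penalty-model-v1",
            "P": self.P.tolist(),
            "G_open": self.G_open,
            "G_extend": self.G_extend,
            "N": self.N.tolist() if self.N is not None else None,
            "eps": self.eps,
            "n_max": self.n_max,
            "l_max": self.l_max,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def load(cls, path: str) -> "PenaltyModel":
        with open(path) as fh:
            obj = json.load(fh)
        if obj.get("format") != "npore-penalty-model-v1":
            raise ValueError(f"{path}: not a penalty model file")
        return cls(P=np.array(obj["P"]), G_open=obj["G_open"],
                   G_extend=obj["G_extend"],
                   N=np.array(obj["N"]) if obj["N"] is not None else None,
                   eps=obj["eps"], n_max=obj["n_max"], l_max=obj["l_max"])


def polymer_error_rate(n: int, copies: int) -> float:
    """Per-polymer probability of a copy-number miscall.

    ``min(0.75, 0.0105 * copies**1.6 / n)``: grows super-linearly with the
    copy count and decreases with unit size (longer units produce a less
    constant signal, so their lengths are easier to call).
    """
    return float(min(0.75, 0.0105 * copies ** 1.6 / n))


def copy_number_confusion_probs(n_max: int = 6, l_max: int = 100,
                                geom_p: float = 0.65,
                                p_lengthen: float = 0.55) -> np.ndarray:
    """Parametric P(observed copies j | expected i, unit size n) tensor.

    Conditional on a miscall the copy-count change has a geometric magnitude
    and lengthens with probability ``p_lengthen``; out-of-range mass is left
    untruncated (it is tiny) so rows sum to slightly less than 1.
    """
    probs = np.zeros((n_max, l_max, l_max))
    for n in range(1, n_max + 1):
        for i in range(l_max):
            err = polymer_error_rate(n, i) if i >= 3 else 0.0
            probs[n - 1, i, i] = 1.0 - err
            for j in range(l_max):
                d = j - i
                if d == 0:
                    continue
                mag_p = geom_p * (1 - geom_p) ** (abs(d) - 1)
                sign_p = p_lengthen if d > 0 else 1 - p_lengthen
                probs[n - 1, i, j] = err * sign_p * mag_p
    return probs
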