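"""Core banded dynamic program for repeat-aware global alignment.

Five matrices are computed in lockstep, one cell at a time, in the order
D, I, M, S, L (Deleting, Inserting, Matching, Shortening, Lengthening):

* ``D[i, j] = min(M[i, j-1] + G_open, D[i, j-1] + G_extend)``
* ``I[i, j] = min(M[i-1, j] + G_open, I[i-1, j] + G_extend)``
* ``M[i, j] = min(M[i-1, j-1] + P[ref[j], read[i]], D, I, S, L at [i, j])``
* S and L hold copy-number transitions and are written *forward*: while
  processing cell (i, j) the shortening candidates land at (i, j+n) (n
  reference bases consumed, none of the read) and the lengthening candidates
  at (i+n, j). Entry from M requires the reference column to start an
  n-polymer (annotation ``l > 0 and idx == 0``); continuation requires a unit
  start of the same polymer; lengthening additionally requires the next n
  read bases to equal the repeat unit. The accumulated penalty of deleting
  (inserting) k whole units of a polymer with l copies is ``N[n, l, l - k]``
  (``N[n, l, l + k]``), charged from the anchor M value.

Every cell stores (value, predecessor, run); traceback happens entirely in M.
All matrices live in a band of half-width ``b`` that follows a seed alignment
path (the read's original CIGAR with every M expanded to I-then-D): cell
(i, j) of the full matrix sits on anti-diagonal d = i + j at in-band offset
``INSs[d] + b - i``, and anything outside the band is +inf. With S and L
disabled the program is exactly Gotoh affine-gap global alignment.
"""

from __future__ import annotations

from math import inf

from .cigar import collapse_cigar, consumed

_B2C = {"A": 0, "C": 1, "G": 2, "T": 3}

#: predecessor codes stored in M
PRED_DIAG, PRED_D, PRED_I, PRED_S, PRED_L, PRED_ORIGIN = 0, 1, 2, 3, 4, 5


class BandTooNarrowError(RuntimeError):
    """The terminal cell is unreachable inside the band; widen the band."""


def inss_from_cigar(cigar: str) -> list[int]:
    """Cumulative insertion counts along the ID-expanded seed path.

    ``inss[d]`` is the number of read bases consumed by the first d ops of
    the expanded path, i.e. the read index of the band centre on
    anti-diagonal d.
    """
    from .banding import expand_to_id  # local import to avoid a cycle

    path = expand_to_id(cigar)
    inss = [0] * (len(path) + 1)
    for d, op in enumerate(path):
        inss[d + 1] = inss[d] + (op == "I")
    return inss


def run_banded(read: str, ref: str, inss: list[int], b: int, model,
               ann_cols: list[list[tuple[int, int, int]]] | None):
    """Forward pass + traceback. Returns ``(raw_ops, score, cell_count)``."""
    nr, nc = len(read), len(ref)
    if len(inss) != nr + nc + 1:
        raise ValueError("seed path length inconsistent with read/ref lengths")
    if inss[-1] != nr:
        raise ValueError("seed path does not consume the whole read")
    W = 2 * b + 1
    ND = nr + nc + 1
    size = ND * W

    Dv = [inf] * size
    Dr = [0] * size
    Iv = [inf] * size
    Ir = [0] * size
    Mv = [inf] * size
    Mp = [-1] * size
    Sv = [inf] * size
    Sr = [0] * size
    Sn = [0] * size
    Sa = [0.0] * size
    Lv = [inf] * size
    Lr = [0] * size
    Ln = [0] * size
    La = [0.0] * size

    Go = float(model.G_open)
    Ge = float(model.G_extend)
    max_sub = model._max_sub
    P = model._P_list
    # 5x5 cost table: code 4 = any non-ACGT base, scored as worst substitution
    P5 = [[P[x][y] for y in range(4)] + [max_sub] for x in range(4)]
    P5.append([max_sub] * 5)
    readc = [_B2C.get(ch, 4) for ch in read]
    refc = [_B2C.get(ch, 4) for ch in ref]

    NL = model._N_list
    l_cap = model.l_max - 1
    use_np = NL is not None and ann_cols is not None

    for d in range(ND):
        ins_d = inss[d]
        base = d * W
        for o in range(W):
            i = ins_d + b - o
            j = d - i
            if i < 0 or i > nr or j < 0 or j > nc:
                continue
            idx = base + o

            # --- D (consume one reference base) ---
            dv = inf
            drun = 0
            if j > 0:
                o2 = inss[d - 1] + b - i
                if 0 <= o2 < W:
                    k2 = (d - 1) * W + o2
                    cand = Mv[k2] + Go
                    if cand < dv:
                        dv = cand
                        drun = 1
                    cand = Dv[k2] + Ge
                    if cand < dv:
                        dv = cand
                        drun = Dr[k2] + 1
            Dv[idx] = dv
            Dr[idx] = drun

            # --- I (consume one read base) ---
            iv = inf
            irun = 0
            if i > 0:
                o2 = inss[d - 1] + b - (i - 1)
                if 0 <= o2 < W:
                    k2 = (d - 1) * W + o2
                    cand = Mv[k2] + Go
                    if cand < iv:
                        iv = cand
                        irun = 1
                    cand = Iv[k2] + Ge
                    if cand < iv:
                        iv = cand
                        irun = Ir[k2] + 1
            Iv[idx] = iv
            Ir[idx] = irun

            # --- M (candidates in tie-break order: diag, S, L, D, I) ---
            mv = inf
            mp = -1
            if i == 0 and j == 0:
                mv = 0.0
                mp = PRED_ORIGIN
            elif i > 0 and j > 0:
                o2 = inss[d - 2] + b - (i - 1)
                if 0 <= o2 < W:
                    cand = Mv[(d - 2) * W + o2] + P5[refc[j - 1]][readc[i - 1]]
                    if cand < mv:
                        mv = cand
                        mp = PRED_DIAG
            sv = Sv[idx]
            if sv < mv:
                mv = sv
                mp = PRED_S
            lv = Lv[idx]
            if lv < mv:
                mv = lv
                mp = PRED_L
            if dv < mv:
                mv = dv
                mp = PRED_D
            if iv < mv:
                mv = iv
                mp = PRED_I
            Mv[idx] = mv
            Mp[idx] = mp

            # --- forward writes into S and L ---
            if use_np and j < nc and ann_cols[j]:
                for n, l, uix in ann_cols[j]:
                    li = l if l <= l_cap else l_cap
                    # shortening: delete ref[j:j+n], land at (i, j+n)
                    if j + n <= nc:
                        o3 = inss[d + n] + b - i
                        if 0 <= o3 < W:
                            k3 = (d + n) * W + o3
                            if uix == 0 and mv < inf:
                                jj = l - 1 if l - 1 <= l_cap else l_cap
                                cost = mv + NL[n - 1][li][jj]
                                if cost < Sv[k3]:
                                    Sv[k3] = cost
                                    Sr[k3] = n
                                    Sn[k3] = n
                                    Sa[k3] = mv
                            if sv < inf and Sn[idx] == n and Sr[idx] == n * uix:
                                done = Sr[idx] // n
                                if done + 1 <= l:
                                    jj = l - 1 - done
                                    if jj > l_cap:
                                        jj = l_cap
                                    cost = Sa[idx] + NL[n - 1][li][jj]
                                    if cost < Sv[k3]:
                                        Sv[k3] = cost
                                        Sr[k3] = Sr[idx] + n
                                        Sn[k3] = n
                                        Sa[k3] = Sa[idx]
                    # lengthening: insert one unit copy, land at (i+n, j);
                    # the next n read bases must equal the repeat unit (c3)
                    if i + n <= nr and read[i:i + n] == ref[j:j + n]:
                        o3 = inss[d + n] + b - (i + n)
                        if 0 <= o3 < W:
                            k3 = (d + n) * W + o3
                            if uix == 0 and mv < inf:
                                jj = l + 1 if l + 1 <= l_cap else l_cap
                                cost = mv + NL[n - 1][li][jj]
                                if cost < Lv[k3]:
                                    Lv[k3] = cost
                                    Lr[k3] = n
                                    Ln[k3] = n
                                    La[k3] = mv
                            if lv < inf and Ln[idx] == n and uix == 0:
                                jj = l + 1 + Lr[idx] // n
                                if jj > l_cap:
                                    jj = l_cap
                                cost = La[idx] + NL[n - 1][li][jj]
                                if cost < Lv[k3]:
                                    Lv[k3] = cost
                                    Lr[k3] = Lr[idx] + n
                                    Ln[k3] = n
                                    La[k3] = La[idx]

    # --- traceback, entirely within M ---
    i, j = nr, nc
    o = inss[nr + nc] + b - i
    if not 0 <= o < W or Mv[(nr + nc) * W + o] == inf:
        raise BandTooNarrowError(
            "terminal cell unreachable within the band; widen the band "
            "(increase b) or fall back to unbanded alignment")
    score = Mv[(nr + nc) * W + o]
    parts: list[str] = []
    while i or j:
        idx = (i + j) * W + (inss[i + j] + b - i)
        p = Mp[idx]
        if p == PRED_DIAG:
            parts.append("M")
            i -= 1
            j -= 1
        elif p == PRED_D:
            g = Dr[idx]
            parts.append("D" * g)
            j -= g
        elif p == PRED_I:
            g = Ir[idx]
            parts.append("I" * g)
            i -= g
        elif p == PRED_S:
            g = Sr[idx]
            parts.append("D" * g)
            j -= g
        elif p == PRED_L:
            g = Lr[idx]
            parts.append("I" * g)
            i -= g
        else:  # pragma: no cover - forward pass guarantees reachability
            raise RuntimeError(f"broken traceback at ({i}, {j})")
    raw = "".join(reversed(parts))
    return raw, score, size


def validate_seed(cigar: str, read: str, ref: str) -> None:
    nread, nref = consumed(cigar)
    if nread != len(read) or nref != len(ref):
        raise ValueError(
            f"seed CIGAR consumes ({nread}, {nref}) but sequences are "
            f"({len(read)}, {len(ref)})")


__all__ = [
    "BandTooNarrowError", "run_banded", "inss_from_cigar", "validate_seed",
    "collapse_cigar",
]
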