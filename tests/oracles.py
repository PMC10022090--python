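"""Independent reference implementations used only as test oracles.

Each of these is deliberately written with a different algorithmic shape
than the package (naive scans, textbook Gotoh, branch-and-bound path
enumeration) so agreement is meaningful.
"""

from __future__ import annotations

from math import inf


# ---------------------------------------------------------------------------
# brute-force repeat scanner

def brute_annotate(seq: str, n_max: int = 6, min_repeats: int = 3):
    """Per-position (l, idx) by directly counting exact unit copies.

    For every position p and unit length n, counts whole copies of
    seq[p:p+n] forward from p and backward before p; the position is an
    annotated unit start iff the total reaches ``min_repeats``.
    """
    L = len(seq)
    l_out = [[0] * L for _ in range(n_max)]
    idx_out = [[0] * L for _ in range(n_max)]
    for n in range(1, n_max + 1):
        for p in range(L):
            unit = seq[p:p + n]
            if len(unit) < n or "N" in unit:
                continue
            fwd = 0
            q = p
            while seq[q:q + n] == unit:
                fwd += 1
                q += n
            back = 0
            q = p - n
            while q >= 0 and seq[q:q + n] == unit:
                back += 1
                q -= n
            total = fwd + back
            if total >= min_repeats:
                l_out[n - 1][p] = total
                idx_out[n - 1][p] = back
    return l_out, idx_out


# ---------------------------------------------------------------------------
# textbook Gotoh affine-gap global aligner (score only)

def gotoh_score(read: str, ref: str, model) -> float:
    nr, nc = len(read), len(ref)
    Go, Ge = model.G_open, model.G_extend
    M = [[inf] * (nc + 1) for _ in range(nr + 1)]
    D = [[inf] * (nc + 1) for _ in range(nr + 1)]
    I = [[inf] * (nc + 1) for _ in range(nr + 1)]
    for i in range(nr + 1):
        for j in range(nc + 1):
            if j > 0:
                D[i][j] = min(M[i][j - 1] + Go, D[i][j - 1] + Ge)
            if i > 0:
                I[i][j] = min(M[i - 1][j] + Go, I[i - 1][j] + Ge)
            if i == 0 and j == 0:
                M[i][j] = 0.0
                continue
            best = inf
            if i > 0 and j > 0:
                best = M[i - 1][j - 1] + model.sub_cost(ref[j - 1], read[i - 1])
            M[i][j] = min(best, D[i][j], I[i][j])
    return M[nr][nc]


# ---------------------------------------------------------------------------
# exhaustive path search over the full model (branch and bound, exact)

def exhaustive_score(read: str, ref: str, model, annotation) -> float:
    """Minimum penalty over every legal path, by depth-first enumeration.

    Paths are token sequences: diagonal steps, affine I/D runs, and whole
    copy-number events (delete/insert k whole units of a polymer anchored at
    the current reference column, lengthening gated on the read actually
    carrying copies of the unit). Branches are pruned against the best
    complete path found so far, which does not affect exactness.
    """
    nr, nc = len(read), len(ref)
    Go, Ge = model.G_open, model.G_extend
    sub = model.sub_cost
    anchors: list[list[tuple[int, int]]] = [[] for _ in range(nc)]
    if model.npoly_enabled and annotation is not None:
        for n in range(1, annotation.params.n_max + 1):
            for start, copies in annotation.anchors(n):
                anchors[start].append((n, copies))

    # initial upper bound: forced-diagonal path plus one terminal gap
    k = min(nr, nc)
    ub = sum(sub(ref[t], read[t]) for t in range(k))
    if nr != nc:
        ub += Go + (abs(nr - nc) - 1) * Ge
    best = [ub + 1e-9]

    def dfs(i: int, j: int, acc: float) -> None:
        if acc >= best[0]:
            return
        if i == nr and j == nc:
            best[0] = acc
            return
        if i < nr and j < nc:
            dfs(i + 1, j + 1, acc + sub(ref[j], read[i]))
        if j < nc and anchors[j]:
            for n, copies in anchors[j]:
                for kk in range(1, copies + 1):
                    if j + kk * n > nc:
                        break
                    dfs(i, j + kk * n, acc + model.n_cost(n, copies, copies - kk))
                kk = 1
                while (i + kk * n <= nr
                       and read[i + (kk - 1) * n:i + kk * n] == ref[j:j + n]):
                    dfs(i + kk * n, j, acc + model.n_cost(n, copies, copies + kk))
                    kk += 1
        g = 1
        while j + g <= nc:
            c = acc + Go + (g - 1) * Ge
            if c >= best[0]:
                break
            dfs(i, j + g, c)
            g += 1
        g = 1
        while i + g <= nr:
            c = acc + Go + (g - 1) * Ge
            if c >= best[0]:
                break
            dfs(i + g, j, c)
            g += 1

    dfs(0, 0, 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# CIGAR consumption counter

def consumed_naive(cigar: str) -> tuple[int, int]:
    import re

    nread = nref = 0
    for count, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        c = int(count)
        if op in "MIS=X":
            nread += c
        if op in "MDN=X":
            nref += c
    return nread, nref
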