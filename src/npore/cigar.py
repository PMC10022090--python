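"""CIGAR string helpers: expansion, collapse, consumption accounting."""

from __future__ import annotations

import re

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: ops that consume read bases / reference bases
READ_OPS = frozenset("MIS=X")
REF_OPS = frozenset("MDN=X")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """``"3M1D"`` -> ``[(3, "M"), (1, "D")]``; validates full coverage."""
    if cigar == "":
        return []
    out = []
    end = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != end:
            raise ValueError(f"malformed CIGAR: {cigar!r}")
        out.append((int(m.group(1)), m.group(2)))
        end = m.end()
    if end != len(cigar):
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return out


def expand_cigar(cigar: str) -> str:
    """Run-length decode: ``"3M1D"`` -> ``"MMMD"``."""
    return "".join(op * count for count, op in parse_cigar(cigar))


def collapse_cigar(ops: str) -> str:
    """Run-length encode a raw op string: ``"MMMDMIMM"`` -> ``"3M1D1M1I2M"``."""
    if not ops:
        return ""
    out = []
    prev = ops[0]
    run = 1
    for op in ops[1:]:
        if op == prev:
            run += 1
        else:
            out.append(f"{run}{prev}")
            prev = op
            run = 1
    out.append(f"{run}{prev}")
    return "".join(out)


def consumed(cigar: str) -> tuple[int, int]:
    """Return ``(read_bases, ref_bases)`` consumed by a CIGAR."""
    nread = nref = 0
    for count, op in parse_cigar(cigar):
        if op in READ_OPS:
            nread += count
        if op in REF_OPS:
            nref += count
    return nread, nref


def simplify_to_mid(cigar: str) -> tuple[str, int, int, int, int]:
    """Reduce an alignment CIGAR to the {M, I, D} core.

    ``=``/``X`` become ``M``; leading/trailing soft (S) and hard (H) clips are
    stripped and returned separately. Returns
    ``(core_cigar, left_soft, right_soft, left_hard, right_hard)``.
    ``N`` and ``P`` ops are not supported here and raise ``ValueError``.
    """
    ops = parse_cigar(cigar)
    lh = rh = ls = rs = 0
    if ops and ops[0][1] == "H":
        lh = ops.pop(0)[0]
    if ops and ops[-1][1] == "H":
        rh = ops.pop()[0]
    if ops and ops[0][1] == "S":
        ls = ops.pop(0)[0]
    if ops and ops[-1][1] == "S":
        rs = ops.pop()[0]
    core = []
    for count, op in ops:
        if op in "=X":
            op = "M"
        if op not in "MID":
            raise ValueError(f"unsupported CIGAR op {op!r} in {cigar!r}")
        core.append(f"{count}{op}")
    return collapse_cigar(expand_cigar("".join(core))), ls, rs, lh, rh
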