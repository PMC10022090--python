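"""Synthetic references, reads, BAMs and phased truth VCFs.

Everything here is seeded and text-first so the rest of the package is
testable without any external data. The generator emulates the error
structure of nanopore R9.4.1 basecalls at the level that matters for
realignment:

* references carry embedded n-polymers at known coordinates on a random
  background (which of course also contains natural short repeats -- those
  participate in the error process too);
* reads acquire copy-number errors inside n-polymers, drawn per polymer from
  a configurable confusion matrix (default: the same parametric family as
  :meth:`npore.model.PenaltyModel.default`), plus uniform substitutions and
  affine-shaped indels elsewhere;
* each read records two CIGARs: a *truth* CIGAR that anchors every
  copy-number indel at its polymer start, and a *naive* CIGAR that mimics a
  minimap2-style aligner by merging an insertion and an equal-length nearby
  deletion into a substitution-heavy all-M stretch. The naive CIGAR is what
  lands in the BAM, giving the realigner something measurable to fix.

Two preset configurations are provided: :func:`penalty_estimation_config`
(homopolymers spaced far apart, copy-number channel isolated, for parameter
recovery) and :func:`realignment_config` (adjacent polymer pairs so merged
indels actually occur, for end-to-end concordance experiments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .annotation import AnnotationParams, NPolymerAnnotation, annotate_reference
from .cigar import collapse_cigar
from .model import copy_number_confusion_probs

BASES = "ACGT"


@dataclass
class SimulationConfig:
    seed: int = 0
    ref_length: int = 3000
    #: embedded polymers as (unit length n, copies l, how many to place)
    polymers: tuple[tuple[int, int, int], ...] = (
        (1, 8, 4), (1, 10, 4), (1, 12, 3), (2, 4, 3), (2, 6, 3),
        (3, 4, 3), (4, 3, 2), (6, 3, 2),
    )
    min_gap: int = 20          # bp of non-repetitive sequence between placements
    sub_rate: float = 0.01
    indel_open_rate: float = 0.002
    indel_extend: float = 0.7  # geometric extension probability
    read_length: int = 120
    depth: int = 10
    merge_window: int = 20     # naive-aligner indel merge distance
    #: optional explicit P(observed | expected) tensor; default parametric
    error_probs: np.ndarray | None = field(default=None, repr=False)
    #: scrub accidental n-polymers from the random background
    clean_background: bool = False
    n_max: int = 6
    l_max: int = 100

    def probs(self) -> np.ndarray:
        if self.error_probs is not None:
            return self.error_probs
        return copy_number_confusion_probs(self.n_max, self.l_max)


#: three-level delta distribution used by the estimation fixture: deep
#: coverage then puts every occupied confusion cell far above the sampling
#: noise floor (row totals >= ~4000, so each occupied cell has s.e. <~ 0.03
#: on the log scale)
_EST_DELTAS = {0: 0.50, -1: 0.26, 1: 0.24}


def penalty_estimation_config(seed: int = 0) -> SimulationConfig:
    """Deep, polymer-rich, well-separated fixture for penalty recovery.

    Only the copy-number error channel is active (no background indels), so
    the measured C_N rows estimate the configured confusion probabilities
    directly; polymers sit far apart so the naive aligner never merges
    events, and the error rows put all their mass on copy changes of +-1.
    """
    return SimulationConfig(
        seed=seed, ref_length=2600,
        polymers=((1, 8, 12), (1, 10, 12), (1, 12, 8), (2, 5, 6), (3, 4, 6)),
        min_gap=40, sub_rate=0.005, indel_open_rate=0.0,
        read_length=150, depth=600, merge_window=0,
        error_probs=spread_error_probs({(1, 8): _EST_DELTAS,
                                        (1, 10): _EST_DELTAS,
                                        (1, 12): _EST_DELTAS,
                                        (2, 5): _EST_DELTAS,
                                        (3, 4): _EST_DELTAS}),
    )


def spread_error_probs(rows: dict[tuple[int, int], dict[int, float]],
                       n_max: int = 6, l_max: int = 100) -> np.ndarray:
    """Explicit confusion tensor from per-(n, copies) delta distributions.

    ``rows[(n, l)] = {delta: prob}`` sets P(observed = l + delta | expected
    l); polymers whose row is not given draw no copy-number errors.
    """
    probs = np.zeros((n_max, l_max, l_max))
    for (n, l), deltas in rows.items():
        for d, p in deltas.items():
            if 0 <= l + d < l_max:
                probs[n - 1, l, l + d] = p
    return probs


#: delta distribution of a long, frequently miscalled homopolymer
#: (diagonal-dominant with a two-sided geometric-like spread)
_HP12_DELTAS = {0: 0.33, -1: 0.27, 1: 0.22, -2: 0.09, 2: 0.06, -3: 0.02, 3: 0.01}


def realignment_config(seed: int = 0) -> SimulationConfig:
    """Adjacent high-error homopolymer pairs for end-to-end realignment.

    Long homopolymers a few bases apart make opposite-sign copy-number
    errors within one read common; the naive aligner merges each such pair
    into a substitution-heavy all-M stretch, which (on top of the deletion
    pileup at polymer starts) pushes junction columns into mixed three-class
    territory. Realignment re-expresses them as copy-number indels anchored
    at the polymer starts.
    """
    return SimulationConfig(
        seed=seed, ref_length=600,
        polymers=((1, 12, 30),),
        min_gap=2, sub_rate=0.003, indel_open_rate=0.0,
        read_length=150, depth=30, merge_window=20,
        error_probs=spread_error_probs({(1, 12): _HP12_DELTAS}),
    )


@dataclass
class SimRead:
    name: str
    pos: int                  # 0-based reference start
    seq: str
    truth_cigar: str          # copy-number indels anchored at polymer starts
    naive_cigar: str          # minimap2-like merged/SNP-heavy representation
    events: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# reference construction

def _random_unit(rng: np.random.Generator, n: int) -> str:
    """Primitive repeat unit with no internal/wrap-around base run >= 3."""
    while True:
        unit = "".join(rng.choice(list(BASES), size=n))
        if n > 1 and len(set(unit)) == 1:
            continue
        if any(unit == unit[k:] + unit[:k] for k in range(1, n)):
            continue  # not primitive
        if max(len(r) for r in _runs(unit * 2)) >= 3:
            continue
        return unit


def _runs(s: str) -> list[str]:
    out, cur = [], s[0]
    for ch in s[1:]:
        if ch == cur[0]:
            cur += ch
        else:
            out.append(cur)
            cur = ch
    out.append(cur)
    return out


def make_reference(config: SimulationConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[str, list[tuple[int, int, int]]]:
    """Random reference with embedded polymers.

    Returns ``(sequence, placements)`` where placements are ``(n, copies,
    start)`` tuples. Placement flanks are chosen so the embedded polymer is
    not accidentally extended by its neighbours.
    """
    rng = rng or np.random.default_rng(config.seed)
    blocks = []
    for n, copies, count in config.polymers:
        blocks.extend((n, copies) for _ in range(count))
    rng.shuffle(blocks)
    total_poly = sum(n * c for n, c in blocks)
    total_gap = config.ref_length - total_poly
    if total_gap < (len(blocks) + 1) * config.min_gap:
        raise ValueError("polymers cannot fit in ref_length with min_gap")
    # distribute gap lengths
    cuts = np.sort(rng.integers(0, total_gap - (len(blocks) + 1) * config.min_gap + 1,
                                size=len(blocks)))
    gaps = np.diff(np.concatenate([[0], cuts, [total_gap - (len(blocks) + 1) * config.min_gap]]))
    gaps = gaps + config.min_gap

    seq_parts: list[str] = []
    placements: list[tuple[int, int, int]] = []
    pos = 0
    for k, (n, copies) in enumerate(blocks):
        g = int(gaps[k])
        seq_parts.append("".join(rng.choice(list(BASES), size=g)))
        pos += g
        unit = _random_unit(rng, n) if n > 1 else rng.choice(list(BASES))
        poly = unit * copies
        # break same-phase extension on the left flank: a backward unit copy
        # would need its last base to match the unit's last base
        left = seq_parts[-1]
        if left and left[-1] == poly[-1]:
            choices = [b for b in BASES if b != poly[-1]]
            seq_parts[-1] = left[:-1] + rng.choice(choices)
        seq_parts.append(poly)
        placements.append((n, copies, pos))
        pos += len(poly)
    tail = int(gaps[-1]) + int(total_gap - gaps.sum())
    seq_parts.append("".join(rng.choice(list(BASES), size=max(config.min_gap, tail))))
    seq = "".join(seq_parts)
    for n, copies, start in placements:
        if start + n * copies < len(seq) and seq[start + n * copies] == seq[start]:
            lst = list(seq)
            choices = [b for b in BASES if b != seq[start + n * copies - n]]
            lst[start + n * copies] = rng.choice(choices)
            seq = "".join(lst)
    if config.clean_background:
        seq = _scrub_background(seq, placements, config, rng)
    return seq, placements


def _scrub_background(seq: str, placements, config, rng) -> str:
    """Mutate bases until no n-polymer exists outside the placements."""
    spans = [(s, s + n * c) for n, c, s in placements]
    params = AnnotationParams(n_max=config.n_max, l_max=config.l_max)
    lst = list(seq)
    for _ in range(200):
        ann = annotate_reference("".join(lst), params)
        dirty = []
        for n in range(1, config.n_max + 1):
            for start, copies in ann.anchors(n):
                end = start + n * copies
                if not any(a <= start and end <= b for a, b in spans):
                    dirty.append((start, end))
        if not dirty:
            return "".join(lst)
        for start, end in dirty:
            p = int(rng.integers(start, end))
            if any(a <= p < b for a, b in spans):
                continue
            lst[p] = rng.choice([c for c in BASES if c != lst[p]])
    raise RuntimeError("could not scrub background repeats")


def disjoint_polymers(ann: NPolymerAnnotation) -> list[tuple[int, int, int]]:
    """Greedy maximal non-overlapping set of annotated polymers.

    Sorted by start (ties: larger span, then smaller n); used to decide
    which polymer "owns" each repetitive stretch when drawing errors.
    Returns ``(n, copies, start)`` tuples.
    """
    cands = []
    for n in range(1, ann.params.n_max + 1):
        for start, copies in ann.anchors(n):
            cands.append((start, -(n * copies), n, copies))
    cands.sort()
    out = []
    prev_end = -1
    for start, negspan, n, copies in cands:
        if start <= prev_end:
            continue
        out.append((n, copies, start))
        prev_end = start - negspan - 1
    return out


# ---------------------------------------------------------------------------
# read simulation

def simulate_reads(ref: str, config: SimulationConfig,
                   annotation: NPolymerAnnotation | None = None) -> list[SimRead]:
    """Simulate reads tiled over the reference at the configured depth."""
    rng = np.random.default_rng(config.seed + 1)
    ann = annotation or annotate_reference(
        ref, AnnotationParams(n_max=config.n_max, l_max=config.l_max))
    polymers = disjoint_polymers(ann)
    probs = config.probs()

    n_reads = max(1, int(round(len(ref) * config.depth / config.read_length)))
    starts = rng.integers(0, max(1, len(ref) - config.read_length + 1),
                          size=n_reads)
    reads = []
    for k, ws in enumerate(sorted(int(s) for s in starts)):
        we = min(len(ref), ws + config.read_length)
        read = _simulate_one(ref, ws, we, polymers, probs, config, rng,
                             name=f"read{k:05d}")
        if read is not None:
            reads.append(read)
    return reads


def _simulate_one(ref, ws, we, polymers, probs, config, rng, name):
    # polymers fully inside the window, 1 bp flanks included
    local = [(n, l, s) for n, l, s in polymers
             if s - 1 >= ws and s + n * l + 1 <= we]
    events = []  # (start, end, kind, payload)
    covered = np.zeros(we - ws, dtype=bool)
    for n, l, s in local:
        covered[s - ws:s + n * l - ws] = True
    for n, l, s in local:
        row = probs[n - 1, min(l, config.l_max - 1)].copy()
        tot = row.sum()
        if tot <= 0:
            continue
        obs = int(rng.choice(len(row), p=row / tot))
        if obs != l:
            events.append((s, s + n * l, "cn", (n, l, obs)))
    p = ws
    while p < we:
        if covered[p - ws]:
            p += 1
            continue
        if config.sub_rate > 0 and rng.random() < config.sub_rate:
            alt = rng.choice([b for b in BASES if b != ref[p]])
            events.append((p, p + 1, "sub", str(alt)))
        elif config.indel_open_rate > 0 and rng.random() < config.indel_open_rate:
            g = int(max(1, min(rng.geometric(1 - config.indel_extend), 10)))
            if rng.random() < 0.5:
                ins = "".join(rng.choice(list(BASES), size=g))
                events.append((p, p + 1, "ins", ins))
            else:
                if p + 1 + g <= we and not covered[p + 1 - ws:p + 1 + g - ws].any():
                    events.append((p, p + 1 + g, "del", g))
                    p += g  # the deleted span can host no further events
        p += 1

    events.sort(key=lambda e: e[0])
    read_parts: list[str] = []
    chunks: list[tuple[str, str, object]] = []  # (truth_ops, kind, event)
    cursor = ws
    for start, end, kind, payload in events:
        if start > cursor:
            seg = ref[cursor:start]
            read_parts.append(seg)
            chunks.append(("M" * len(seg), "copy", None))
        if kind == "cn":
            n, l, obs = payload
            unit = ref[start:start + n]
            if obs < l:
                k = l - obs
                read_parts.append(ref[start + k * n:end])
                chunks.append(("D" * (k * n) + "M" * (obs * n), "cn",
                               (start, end, -k * n)))
            else:
                k = obs - l
                read_parts.append(unit * k + ref[start:end])
                chunks.append(("I" * (k * n) + "M" * (l * n), "cn",
                               (start, end, k * n)))
        elif kind == "sub":
            read_parts.append(payload)
            chunks.append(("M", "sub", None))
        elif kind == "ins":
            read_parts.append(ref[start] + payload)
            chunks.append(("M" + "I" * len(payload), "indel", None))
        elif kind == "del":
            read_parts.append(ref[start])
            chunks.append(("M" + "D" * (end - start - 1), "indel", None))
        cursor = end
    if cursor < we:
        seg = ref[cursor:we]
        read_parts.append(seg)
        chunks.append(("M" * len(seg), "copy", None))

    read = "".join(read_parts)
    if not read:
        return None
    truth = "".join(ops for ops, _, _ in chunks)
    naive = _naive_ops(chunks, config.merge_window)
    return SimRead(name=name, pos=ws, seq=read,
                   truth_cigar=collapse_cigar(truth),
                   naive_cigar=collapse_cigar(naive),
                   events=events)


def _naive_ops(chunks, merge_window: int) -> str:
    """Merge an insertion-type and an equal-sized deletion-type copy-number
    event within ``merge_window`` bp into an all-M stretch."""
    merged_with: dict[int, int] = {}
    if merge_window > 0:
        open_events: list[tuple[int, int, int]] = []  # (chunk idx, end, delta)
        for ci, (ops, kind, ev) in enumerate(chunks):
            if kind != "cn":
                if kind == "indel":
                    open_events.clear()  # other indels break mergeability
                continue
            start, end, delta = ev
            # pair only with the most recent open event so merged regions
            # nest and never contain an unmerged copy-number indel
            if (open_events and open_events[-1][2] == -delta
                    and start - open_events[-1][1] <= merge_window):
                cj, _, _ = open_events.pop()
                merged_with[cj] = ci
            else:
                open_events.append((ci, end, delta))
    out = []
    skip_until = -1
    for ci, (ops, kind, ev) in enumerate(chunks):
        if ci <= skip_until:
            continue
        if ci in merged_with:
            # everything from here through the partner chunk becomes M;
            # within the region inserted and deleted bases cancel exactly
            cj = merged_with[ci]
            nbases = sum(len(chunks[t][0]) - chunks[t][0].count("I")
                         for t in range(ci, cj + 1))
            out.append("M" * nbases)
            skip_until = cj
            continue
        out.append(ops)
    return "".join(out)


# ---------------------------------------------------------------------------
# phased truth variants

def make_phased_truth(ref: str, config: SimulationConfig,
                      snp_count: int = 12, cn_indel_count: int = 8,
                      annotation: NPolymerAnnotation | None = None):
    """Random phased small variants: SNPs plus polymer copy-number indels.

    Returns VCF-style records ``(pos0, ref_allele, alt_allele, genotype)``
    with 0-based positions, non-overlapping including 1 bp of slack.
    """
    rng = np.random.default_rng(config.seed + 2)
    ann = annotation or annotate_reference(
        ref, AnnotationParams(n_max=config.n_max, l_max=config.l_max))
    polymers = disjoint_polymers(ann)
    gts = ["1|0", "0|1", "1|1"]
    used: list[tuple[int, int]] = []
    records = []

    cands = [pl for pl in polymers if pl[2] > 0]
    rng.shuffle(cands)
    for n, l, s in cands[:cn_indel_count]:
        span = (s - 2, s + n * l + 2)
        if any(a < span[1] and span[0] < b for a, b in used):
            continue
        delete = rng.random() < 0.5
        anchor = s - 1
        unit = ref[s:s + n]
        if delete:
            rec = (anchor, ref[anchor:anchor + 1 + n], ref[anchor], gts[rng.integers(3)])
        else:
            rec = (anchor, ref[anchor], ref[anchor] + unit, gts[rng.integers(3)])
        records.append(rec)
        used.append(span)

    attempts = 0
    placed = 0
    while placed < snp_count and attempts < snp_count * 50:
        attempts += 1
        p = int(rng.integers(1, len(ref) - 1))
        if any(a <= p < b for a, b in used):
            continue
        alt = rng.choice([b for b in BASES if b != ref[p]])
        records.append((p, ref[p], str(alt), gts[rng.integers(3)]))
        used.append((p - 1, p + 2))
        placed += 1
    records.sort()
    return records


# ---------------------------------------------------------------------------
# writers

def write_fasta(path: str, contig: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for k in range(0, len(seq), width):
            fh.write(seq[k:k + width] + "\n")


def write_bam(path: str, reads: list[SimRead], contig: str, ref_len: int,
              cigar: str = "naive", index: bool = True) -> None:
    """Write sorted reads (naive or truth CIGARs) to a BAM and index it."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": contig, "LN": ref_len}]}
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for read in sorted(reads, key=lambda r: (r.pos, r.name)):
            a = pysam.AlignedSegment()
            a.query_name = read.name
            a.query_sequence = read.seq
            a.flag = 0
            a.reference_id = 0
            a.reference_start = read.pos
            a.mapping_quality = 60
            a.cigarstring = read.naive_cigar if cigar == "naive" else read.truth_cigar
            a.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
            bam.write(a)
    if index:
        pysam.index(path)


def write_vcf(path: str, contig: str, ref_len: int, records) -> None:
    """Write phased ``(pos0, ref, alt, gt)`` records as an uncompressed VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={ref_len}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for pos0, ref_allele, alt_allele, gt in records:
            fh.write(f"{contig}\t{pos0 + 1}\t.\t{ref_allele}\t{alt_allele}"
                     f"\t.\tPASS\t.\tGT\t{gt}\n")
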