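"""Truth VCF standardization.

A phased truth VCF can express the same haplotype sequence in many ways
(e.g. a SNP pair inside a homopolymer versus an insertion plus a deletion).
The repeat-aware aligner systematically prefers copy-number indel
representations, so for training/evaluation consistency the truth set is
rewritten in that same representation *without changing the haplotype
sequences*: each phased haplotype is materialised as a sequence, treated as
a read and realigned to the reference with the repeat-aware banded aligner
(its construction CIGAR seeding the band), and the resulting edits are
parsed back into VCF records. Applying the standardized VCF reproduces the
original haplotype sequences byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import pysam

from ._engine import BandTooNarrowError
from .align import align
from .banding import DEFAULT_BAND, banded_align
from .cigar import collapse_cigar, parse_cigar
from .model import PenaltyModel

DEFAULT_ANCHOR = 200  # minimum variant-free stretch at which contigs are chunked

#: a phased record: (0-based pos, ref allele, alt alleles, (hap1, hap2) indices)
VcfRecord = tuple[int, str, tuple[str, ...], tuple[int, int]]


@dataclass
class HaplotypeSequence:
    contig: str
    hap: int              # 0 or 1
    seq: str
    cigar: str            # construction CIGAR relative to the reference

    def __post_init__(self) -> None:
        nread = sum(c for c, o in parse_cigar(self.cigar) if o in "MI")
        if nread != len(self.seq):
            raise ValueError("construction CIGAR inconsistent with sequence")


# ---------------------------------------------------------------------------
# VCF in/out

def read_vcf_records(path: str) -> dict[str, list[VcfRecord]]:
    """Load a fully phased VCF; rejects unphased or conflicting records."""
    out: dict[str, list[VcfRecord]] = {}
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            sample = rec.samples[0]
            gt = sample["GT"]
            if gt is None or len(gt) != 2 or None in gt:
                raise ValueError(f"missing genotype at {rec.chrom}:{rec.pos}")
            if not sample.phased and gt[0] != gt[1]:
                raise ValueError(f"unphased heterozygote at {rec.chrom}:{rec.pos}")
            alts = tuple(rec.alts or ())
            out.setdefault(rec.chrom, []).append(
                (rec.start, rec.ref.upper(), tuple(a.upper() for a in alts),
                 (gt[0], gt[1])))
    for records in out.values():
        records.sort()
    return out


def write_standardized_vcf(path: str, contigs: dict[str, int],
                           records_by_contig: dict[str, list[VcfRecord]]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in contigs.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for contig, records in records_by_contig.items():
            for pos0, ref, alts, gt in records:
                fh.write(f"{contig}\t{pos0 + 1}\t.\t{ref}\t{','.join(alts)}"
                         f"\t.\tPASS\t.\tGT\t{gt[0]}|{gt[1]}\n")


# ---------------------------------------------------------------------------
# applying a phased VCF

def apply_phased_vcf(ref_seqs: dict[str, str],
                     records_by_contig: dict[str, list[VcfRecord]]
                     ) -> dict[str, tuple[HaplotypeSequence, HaplotypeSequence]]:
    """Materialise both haplotype sequences (and construction CIGARs)."""
    out = {}
    for contig, ref in ref_seqs.items():
        records = records_by_contig.get(contig, [])
        haps = tuple(
            _apply_one(contig, ref, records, hap) for hap in (0, 1))
        out[contig] = haps  # type: ignore[assignment]
    return out


def _apply_one(contig: str, ref: str, records: list[VcfRecord],
               hap: int) -> HaplotypeSequence:
    parts: list[str] = []
    ops: list[str] = []
    cursor = 0
    for pos0, ref_allele, alts, gt in records:
        ai = gt[hap]
        if ai == 0:
            continue
        if pos0 < cursor:
            raise ValueError(
                f"overlapping records on haplotype {hap + 1} at {contig}:{pos0 + 1}")
        if ref[pos0:pos0 + len(ref_allele)] != ref_allele:
            raise ValueError(
                f"REF mismatch at {contig}:{pos0 + 1}: VCF says {ref_allele!r}")
        try:
            allele = alts[ai - 1]
        except IndexError:
            raise ValueError(f"allele index {ai} out of range at {contig}:{pos0 + 1}")
        parts.append(ref[cursor:pos0])
        ops.append("M" * (pos0 - cursor))
        parts.append(allele)
        k = min(len(ref_allele), len(allele))
        ops.append("M" * k)
        if len(allele) > k:
            ops.append("I" * (len(allele) - k))
        if len(ref_allele) > k:
            ops.append("D" * (len(ref_allele) - k))
        cursor = pos0 + len(ref_allele)
    parts.append(ref[cursor:])
    ops.append("M" * (len(ref) - cursor))
    return HaplotypeSequence(contig=contig, hap=hap, seq="".join(parts),
                             cigar=collapse_cigar("".join(ops)))


# ---------------------------------------------------------------------------
# standardization

def standardize(ref_seqs: dict[str, str],
                records_by_contig: dict[str, list[VcfRecord]],
                model: PenaltyModel, b: int = DEFAULT_BAND,
                anchor_len: int = DEFAULT_ANCHOR
                ) -> dict[str, list[VcfRecord]]:
    """Rewrite phased truth variants in the aligner's preferred representation.

    Contigs are processed in chunks split at variant-free stretches of at
    least ``anchor_len`` bp, so whole-contig alignment is never needed; the
    chunks are independent, so the output equals what a single whole-contig
    realignment would produce.
    """
    out: dict[str, list[VcfRecord]] = {}
    for contig, ref in ref_seqs.items():
        records = records_by_contig.get(contig, [])
        merged: list[VcfRecord] = []
        for cs, ce, chunk_records in _chunks(ref, records, anchor_len):
            per_hap: list[list[tuple[int, str, str]]] = []
            for hap in (0, 1):
                hs = _apply_one(contig, ref[cs:ce],
                                [(p - cs, r, a, g) for p, r, a, g in chunk_records],
                                hap)
                if hs.seq == ref[cs:ce]:
                    per_hap.append([])
                    continue
                try:
                    res = banded_align(hs.seq, ref[cs:ce], hs.cigar, model, b=b)
                except BandTooNarrowError:
                    res = align(hs.seq, ref[cs:ce], model)
                per_hap.append(_edits_to_records(ref[cs:ce], hs.seq, res.cigar, cs))
            merged.extend(_merge_haplotypes(per_hap[0], per_hap[1]))
        merged.sort()
        out[contig] = merged
    return out


def _chunks(ref: str, records: list[VcfRecord], anchor_len: int):
    """Split [0, len(ref)) at the midpoints of long variant-free gaps."""
    if not records:
        yield 0, len(ref), []
        return
    spans = [(p, p + len(r)) for p, r, _, _ in records]
    bounds = [0]
    for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
        if s1 - e0 >= anchor_len:
            bounds.append((e0 + s1) // 2)
    bounds.append(len(ref))
    for cs, ce in zip(bounds, bounds[1:]):
        chunk_records = [rec for rec in records if cs <= rec[0] < ce]
        yield cs, ce, chunk_records


def _edits_to_records(ref_chunk: str, hap_chunk: str, cigar: str,
                      offset: int) -> list[tuple[int, str, str]]:
    """Parse contiguous edit runs of an alignment into (pos, REF, ALT)."""
    runs: list[tuple[int, int, str]] = []  # (ref_lo, ref_hi, alt)
    i = j = 0
    cur: tuple[int, int, str] | None = None
    for count, op in parse_cigar(cigar):
        if op == "M":
            for t in range(count):
                if hap_chunk[i] == ref_chunk[j]:
                    if cur is not None:
                        runs.append(cur)
                        cur = None
                else:
                    cur = (j, j + 1, hap_chunk[i]) if cur is None else \
                        (cur[0], j + 1, cur[2] + hap_chunk[i])
                i += 1
                j += 1
        elif op == "I":
            ins = hap_chunk[i:i + count]
            cur = (j, j, ins) if cur is None else (cur[0], cur[1], cur[2] + ins)
            i += count
        elif op == "D":
            cur = (j, j + count, "") if cur is None else (cur[0], j + count, cur[2])
            j += count
    if cur is not None:
        runs.append(cur)

    records = []
    for lo, hi, alt in runs:
        ref_run = ref_chunk[lo:hi]
        if len(ref_run) == len(alt) and len(alt) > 0:
            records.append((offset + lo, ref_run, alt))
        elif lo > 0:
            # anchor base on the left, standard VCF indel convention
            records.append((offset + lo - 1,
                            ref_chunk[lo - 1] + ref_run,
                            ref_chunk[lo - 1] + alt))
        elif hi < len(ref_chunk):
            # run at the chunk edge: anchor on the right instead
            records.append((offset + lo, ref_run + ref_chunk[hi],
                            alt + ref_chunk[hi]))
        else:
            # degenerate whole-chunk edit; emit without an anchor base
            records.append((offset + lo, ref_run, alt))
    return records


def _merge_haplotypes(rec1: list[tuple[int, str, str]],
                      rec2: list[tuple[int, str, str]]) -> list[VcfRecord]:
    """Combine per-haplotype edits into genotyped records.

    Identical (pos, REF, ALT) on both haplotypes becomes 1|1; identical
    (pos, REF) with different ALTs becomes a multi-allelic 1|2; anything
    else is emitted as a separate phased record.
    """
    by_key: dict[tuple[int, str], list[tuple[str, int]]] = {}
    for alt_pos in rec1:
        by_key.setdefault((alt_pos[0], alt_pos[1]), []).append((alt_pos[2], 0))
    for alt_pos in rec2:
        by_key.setdefault((alt_pos[0], alt_pos[1]), []).append((alt_pos[2], 1))
    out: list[VcfRecord] = []
    for (pos, ref_allele), items in sorted(by_key.items()):
        if len(items) == 2:
            (a1, _), (a2, _) = items
            if a1 == a2:
                out.append((pos, ref_allele, (a1,), (1, 1)))
            else:
                out.append((pos, ref_allele, (a1, a2), (1, 2)))
        else:
            alt, hap = items[0]
            gt = (1, 0) if hap == 0 else (0, 1)
            out.append((pos, ref_allele, (alt,), gt))
    return out


def standardize_vcf_file(vcf_path: str, ref_path: str, model: PenaltyModel,
                         out_path: str, b: int = DEFAULT_BAND,
                         anchor_len: int = DEFAULT_ANCHOR) -> None:
    """File-level wrapper: FASTA + phased VCF in, standardized VCF out."""
    with pysam.FastaFile(ref_path) as fa:
        ref_seqs = {c: fa.fetch(c).upper() for c in fa.references}
    records = read_vcf_records(vcf_path)
    std = standardize(ref_seqs, records, model, b=b, anchor_len=anchor_len)
    write_standardized_vcf(out_path, {c: len(s) for c, s in ref_seqs.items()}, std)
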