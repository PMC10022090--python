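"""BAM-in/BAM-out realignment.

Mapping is trusted: each read keeps its POS and is globally realigned against
the reference window its original CIGAR spans, inside a follow-band around
the original alignment path. Only the CIGAR (and the NM/MD tags derived from
it) changes; sequence, qualities, names, flags and sort order pass through
bit-identical. Secondary/supplementary/unmapped records are not realigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from multiprocessing import Pool

import pysam

from ._engine import BandTooNarrowError
from .align import align
from .annotation import annotate_reference
from .banding import DEFAULT_BAND, banded_align
from .cigar import consumed, simplify_to_mid
from .model import PenaltyModel

log = logging.getLogger(__name__)

#: reads longer than this never retry unbanded after a band failure
UNBANDED_RETRY_CAP = 2000


@dataclass
class RealignStats:
    total: int = 0
    realigned: int = 0
    passthrough: int = 0
    skipped_contig: int = 0
    band_failures: int = 0
    counters: dict = field(default_factory=dict)


def realign_bam(in_path: str, ref_path: str, model: PenaltyModel,
                out_path: str, band: int = DEFAULT_BAND, threads: int = 1,
                region: str | None = None) -> RealignStats:
    """Realign every eligible primary alignment of a coordinate-sorted BAM.

    Work is partitioned into deterministic read batches, so output records
    are identical for any worker count. Returns per-stage counters.
    """
    stats = RealignStats()
    fasta = pysam.FastaFile(ref_path)
    contigs = set(fasta.references)

    with pysam.AlignmentFile(in_path) as bam:
        header = bam.header.to_dict()
        records = list(bam.fetch(region=region) if region else bam)

    tasks = []  # (record index, read core seq, window seq, core cigar)
    prepared: list[tuple] = []
    for ridx, rec in enumerate(records):
        stats.total += 1
        if (rec.is_unmapped or rec.is_secondary or rec.is_supplementary
                or rec.cigarstring is None):
            stats.passthrough += 1
            continue
        if rec.reference_name not in contigs:
            stats.skipped_contig += 1
            log.warning("contig %s not in reference; read %s passed through",
                        rec.reference_name, rec.query_name)
            continue
        try:
            core, ls, rs, _, _ = simplify_to_mid(rec.cigarstring)
        except ValueError:
            stats.passthrough += 1
            continue
        seq = rec.query_sequence
        core_seq = seq[ls:len(seq) - rs] if rs else seq[ls:]
        _, nref = consumed(core)
        window = fasta.fetch(rec.reference_name, rec.reference_start,
                             rec.reference_start + nref).upper()
        tasks.append((ridx, core_seq, window, core))

    worker = _Worker(model, band)
    if threads > 1 and len(tasks) > 1:
        with Pool(threads) as pool:
            results = pool.map(worker, tasks, chunksize=32)
    else:
        results = [worker(t) for t in tasks]

    for (ridx, _, _, _), (new_core, band_failed) in zip(tasks, results):
        rec = records[ridx]
        if new_core is None:
            stats.passthrough += 1
            if band_failed:
                stats.band_failures += 1
                log.warning("band too narrow for read %s; original CIGAR kept",
                            rec.query_name)
            continue
        stats.band_failures += band_failed
        _apply_cigar(rec, new_core, fasta)
        stats.realigned += 1

    with pysam.AlignmentFile(out_path, _mode_for(out_path), header=header) as out:
        for rec in records:
            out.write(rec)
    fasta.close()
    return stats


class _Worker:
    """Picklable realignment callable shared across worker processes."""

    def __init__(self, model: PenaltyModel, band: int):
        self.model = model
        self.band = band

    def __call__(self, task):
        _, core_seq, window, core = task
        ann = annotate_reference(window, self.model.annotation_params()) \
            if self.model.npoly_enabled else None
        try:
            res = banded_align(core_seq, window, core, self.model,
                               annotation=ann, b=self.band)
            return res.cigar, False
        except BandTooNarrowError:
            if len(core_seq) <= UNBANDED_RETRY_CAP:
                res = align(core_seq, window, self.model, annotation=ann)
                return res.cigar, True
            return None, True


def _apply_cigar(rec, new_core: str, fasta) -> None:
    _, ls, rs, lh, rh = simplify_to_mid(rec.cigarstring)
    parts = []
    if lh:
        parts.append(f"{lh}H")
    if ls:
        parts.append(f"{ls}S")
    parts.append(new_core)
    if rs:
        parts.append(f"{rs}S")
    if rh:
        parts.append(f"{rh}H")
    rec.cigarstring = "".join(parts)
    nm, md = _nm_md(rec, fasta)
    rec.set_tag("NM", nm)
    rec.set_tag("MD", md)


def _nm_md(rec, fasta) -> tuple[int, str]:
    """Recompute edit distance and MD tag for the updated CIGAR."""
    seq = rec.query_sequence
    ref = fasta.fetch(rec.reference_name, rec.reference_start,
                      rec.reference_start + rec.reference_length).upper()
    i = j = 0
    nm = 0
    md_parts: list[str] = []
    match_run = 0
    for op, count in rec.cigartuples:  # pysam order: (operation, length)
        code = "MIDNSHP=X"[op]
        if code in "M=X":
            for t in range(count):
                if seq[i + t] == ref[j + t]:
                    match_run += 1
                else:
                    nm += 1
                    md_parts.append(f"{match_run}{ref[j + t]}")
                    match_run = 0
            i += count
            j += count
        elif code == "I":
            nm += count
            i += count
        elif code == "D":
            nm += count
            md_parts.append(f"{match_run}^{ref[j:j + count]}")
            match_run = 0
            j += count
        elif code == "S":
            i += count
    md_parts.append(str(match_run))
    return nm, "".join(md_parts)


def _mode_for(path: str) -> str:
    return "w" if path.endswith(".sam") else "wb"
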