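"""Synthetic data generator."""

import numpy as np
import pytest

from npore.annotation import annotate_reference
from npore.cigar import consumed, expand_cigar
from npore.model import count_confusions
from npore.simulate import (SimulationConfig, make_phased_truth, make_reference,
                            penalty_estimation_config, realignment_config,
                            simulate_reads, spread_error_probs, write_bam,
                            write_fasta, write_vcf)


def _small_config(**kw):
    defaults = dict(seed=5, ref_length=400,
                    polymers=((1, 8, 2), (2, 4, 2), (3, 4, 1)),
                    min_gap=15, read_length=80, depth=6)
    defaults.update(kw)
    return SimulationConfig(**defaults)


def test_reference_contains_requested_polymers():
    cfg = _small_config()
    ref, placements = make_reference(cfg)
    assert len(ref) == cfg.ref_length
    assert len(placements) == 5
    ann = annotate_reference(ref)
    for n, copies, start in placements:
        unit = ref[start:start + n]
        assert ref[start:start + n * copies] == unit * copies
        assert ann.l_of(n, start) == copies    # not extended by flanks
        assert ann.idx_of(n, start) == 0


def test_zero_polymer_clean_background_annotates_nothing():
    cfg = SimulationConfig(seed=3, ref_length=200, polymers=(),
                           min_gap=5, clean_background=True)
    ref, placements = make_reference(cfg)
    assert placements == []
    ann = annotate_reference(ref)
    for n in range(1, 7):
        assert not ann.l[n - 1].any()


def test_polymers_must_fit():
    with pytest.raises(ValueError, match="fit"):
        make_reference(SimulationConfig(ref_length=50,
                                        polymers=((1, 30, 3),), min_gap=10))


def test_zero_error_rates_give_reference_reads():
    cfg = _small_config(sub_rate=0.0, indel_open_rate=0.0,
                        error_probs=np.zeros((6, 100, 100)))
    ref, _ = make_reference(cfg)
    reads = simulate_reads(ref, cfg)
    assert reads
    for read in reads:
        assert read.seq == ref[read.pos:read.pos + len(read.seq)]
        assert read.truth_cigar == f"{len(read.seq)}M"
        assert read.naive_cigar == read.truth_cigar


def test_cigars_consistent_with_sequences():
    cfg = realignment_config(seed=11)
    ref, _ = make_reference(cfg)
    reads = simulate_reads(ref, cfg)
    for read in reads:
        for cig in (read.truth_cigar, read.naive_cigar):
            nread, nref = consumed(cig)
            assert nread == len(read.seq)
        assert consumed(read.truth_cigar)[1] == consumed(read.naive_cigar)[1]


def test_seed_determinism():
    cfg = _small_config()
    ref1, p1 = make_reference(cfg)
    ref2, p2 = make_reference(_small_config())
    assert ref1 == ref2 and p1 == p2
    r1 = simulate_reads(ref1, cfg)
    r2 = simulate_reads(ref2, _small_config())
    assert [(a.name, a.pos, a.seq, a.naive_cigar) for a in r1] \
        == [(b.name, b.pos, b.seq, b.naive_cigar) for b in r2]
    assert make_phased_truth(ref1, cfg) == make_phased_truth(ref2, _small_config())


def test_measured_error_frequencies_match_configured(rng):
    """Homopolymer copy-number error rates over many reads sit inside
    binomial confidence bounds of the configured distribution."""
    deltas = {0: 0.6, -1: 0.25, 1: 0.15}
    cfg = SimulationConfig(seed=9, ref_length=1200, polymers=((1, 10, 8),),
                           min_gap=25, sub_rate=0.0, indel_open_rate=0.0,
                           read_length=100, depth=150,
                           error_probs=spread_error_probs({(1, 10): deltas}))
    ref, placements = make_reference(cfg)
    reads = simulate_reads(ref, cfg)
    # count events per spanning polymer directly from truth CIGARs
    counts = {d: 0 for d in deltas}
    spans = 0
    for read in reads:
        _, nref = consumed(read.truth_cigar)
        i = j = 0
        del_pos = set()
        ins_at = {}
        for op in expand_cigar(read.truth_cigar):
            if op == "M":
                i += 1
                j += 1
            elif op == "I":
                ins_at[j - 1] = ins_at.get(j - 1, 0) + 1
                i += 1
            else:
                del_pos.add(j)
                j += 1
        for n, copies, start in placements:
            lo, hi = start - read.pos, start - read.pos + copies
            if lo - 1 < 0 or hi + 1 > nref:
                continue
            net = sum(g for k, g in ins_at.items() if lo - 1 <= k <= hi - 1) \
                - sum(1 for p in del_pos if lo <= p < hi)
            if net in counts:
                counts[net] += 1
                spans += 1
    assert spans > 1000
    for d, p in deltas.items():
        phat = counts[d] / spans
        se = np.sqrt(p * (1 - p) / spans)
        assert abs(phat - p) < 4 * se + 1e-3, (d, phat, p)


def test_confusion_counts_recover_configured_probs():
    """count_confusions on the naive BAM CIGARs reproduces the configured
    homopolymer confusion rows up to sampling error."""
    cfg = penalty_estimation_config(seed=4)
    ref, _ = make_reference(cfg)
    ann = annotate_reference(ref)
    reads = simulate_reads(ref, cfg, annotation=ann)
    items = [(r.seq, ref[r.pos:r.pos + consumed(r.naive_cigar)[1]],
              r.naive_cigar, r.pos) for r in reads]
    cc = count_confusions(items, ann)
    probs = cfg.probs()
    for l in (8, 10, 12):
        row = cc.C_N[0, l]
        tot = row.sum()
        assert tot > 1000
        prow = probs[0, l] / probs[0, l].sum()
        for j in (l - 1, l, l + 1):
            phat = row[j] / tot
            se = np.sqrt(prow[j] * (1 - prow[j]) / tot)
            assert abs(phat - prow[j]) < 4 * se + 1e-3


def test_writers_produce_readable_files(tmp_path):
    import pysam

    cfg = _small_config()
    ref, _ = make_reference(cfg)
    reads = simulate_reads(ref, cfg)
    truth = make_phased_truth(ref, cfg)
    write_fasta(str(tmp_path / "r.fa"), "c1", ref)
    write_bam(str(tmp_path / "r.bam"), reads, "c1", len(ref))
    write_vcf(str(tmp_path / "t.vcf"), "c1", len(ref), truth)
    with pysam.FastaFile(str(tmp_path / "r.fa")) as fa:
        assert fa.fetch("c1") == ref
    with pysam.AlignmentFile(str(tmp_path / "r.bam")) as bam:
        recs = list(bam)
        assert len(recs) == len(reads)
        assert all(r.reference_start <= s.reference_start
                   for r, s in zip(recs, recs[1:]))
    with pysam.VariantFile(str(tmp_path / "t.vcf")) as vcf:
        assert len(list(vcf)) == len(truth)
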