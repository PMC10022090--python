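"""BAM realignment pipeline."""

import numpy as np
import pysam
import pytest

from npore.align import score_cigar
from npore.cigar import consumed
from npore.model import PenaltyModel
from npore.realign import realign_bam
from npore.simulate import (SimRead, make_reference, realignment_config,
                            simulate_reads, write_bam, write_fasta)


@pytest.fixture(scope="module")
def fixture_paths(tmp_path_factory):
    d = tmp_path_factory.mktemp("realign")
    cfg = realignment_config(seed=2)
    ref, _ = make_reference(cfg)
    reads = simulate_reads(ref, cfg)[:60]
    write_fasta(str(d / "ref.fa"), "sim1", ref)
    write_bam(str(d / "in.bam"), reads, "sim1", len(ref))
    return d, ref


def test_exact_reads_keep_their_cigars(tmp_path, default_model):
    ref = "GATTACA" * 20
    reads = [SimRead(f"r{i}", i * 5, ref[i * 5:i * 5 + 60], "60M", "60M")
             for i in range(10)]
    write_fasta(str(tmp_path / "ref.fa"), "c1", ref)
    write_bam(str(tmp_path / "in.bam"), reads, "c1", len(ref))
    stats = realign_bam(str(tmp_path / "in.bam"), str(tmp_path / "ref.fa"),
                        default_model, str(tmp_path / "out.bam"))
    assert stats.realigned == 10
    with pysam.AlignmentFile(str(tmp_path / "out.bam")) as bam:
        for rec in bam:
            assert rec.cigarstring == "60M"


def test_read_fields_pass_through_unchanged(fixture_paths, default_model, tmp_path):
    d, ref = fixture_paths
    out = str(tmp_path / "out.bam")
    realign_bam(str(d / "in.bam"), str(d / "ref.fa"), default_model, out)
    with pysam.AlignmentFile(str(d / "in.bam")) as fin, \
            pysam.AlignmentFile(out) as fout:
        for a, b in zip(fin, fout):
            assert a.query_name == b.query_name
            assert a.query_sequence == b.query_sequence
            assert a.reference_start == b.reference_start
            assert a.flag == b.flag
            assert list(a.query_qualities) == list(b.query_qualities)
            nread, nref = consumed(b.cigarstring)
            assert nread == len(b.query_sequence)
            assert nref == a.reference_length  # window span preserved


def test_worker_count_does_not_change_output(fixture_paths, default_model, tmp_path):
    d, _ = fixture_paths
    out1 = str(tmp_path / "o1.bam")
    out2 = str(tmp_path / "o2.bam")
    realign_bam(str(d / "in.bam"), str(d / "ref.fa"), default_model, out1, threads=1)
    realign_bam(str(d / "in.bam"), str(d / "ref.fa"), default_model, out2, threads=3)
    with pysam.AlignmentFile(out1) as f1, pysam.AlignmentFile(out2) as f2:
        for a, b in zip(f1, f2):
            assert a.to_string() == b.to_string()


def test_scores_never_increase_on_second_pass(fixture_paths, default_model, tmp_path):
    """Realignment is score-idempotent: a second pass finds nothing better."""
    d, ref = fixture_paths
    out1 = str(tmp_path / "p1.bam")
    out2 = str(tmp_path / "p2.bam")
    realign_bam(str(d / "in.bam"), str(d / "ref.fa"), default_model, out1)
    pysam.index(out1)
    realign_bam(out1, str(d / "ref.fa"), default_model, out2)
    with pysam.AlignmentFile(out1) as f1, pysam.AlignmentFile(out2) as f2:
        for a, b in zip(f1, f2):
            window = ref[a.reference_start:a.reference_start + a.reference_length]
            s1 = score_cigar(a.query_sequence, window, a.cigarstring, default_model)
            s2 = score_cigar(b.query_sequence, window, b.cigarstring, default_model)
            assert s2 <= s1 + 1e-9


def test_realignment_lowers_or_keeps_alignment_scores(fixture_paths, default_model,
                                                      tmp_path):
    d, ref = fixture_paths
    out = str(tmp_path / "out.bam")
    realign_bam(str(d / "in.bam"), str(d / "ref.fa"), default_model, out)
    improved = 0
    with pysam.AlignmentFile(str(d / "in.bam")) as fin, \
            pysam.AlignmentFile(out) as fout:
        for a, b in zip(fin, fout):
            window = ref[a.reference_start:a.reference_start + a.reference_length]
            before = score_cigar(a.query_sequence, window, a.cigarstring,
                                 default_model)
            after = score_cigar(b.query_sequence, window, b.cigarstring,
                                default_model)
            assert after <= before + 1e-9
            improved += after < before - 1e-9
    assert improved > 0


def test_nm_md_tags_recomputed(fixture_paths, default_model, tmp_path):
    d, ref = fixture_paths
    out = str(tmp_path / "out.bam")
    realign_bam(str(d / "in.bam"), str(d / "ref.fa"), default_model, out)
    with pysam.AlignmentFile(out) as bam:
        for rec in bam:
            seq = rec.query_sequence
            window = ref[rec.reference_start:rec.reference_start
                         + rec.reference_length]
            nm = 0
            i = j = 0
            for op, count in rec.cigartuples:
                code = "MIDNSHP=X"[op]
                if code == "M":
                    nm += sum(seq[i + t] != window[j + t] for t in range(count))
                    i += count
                    j += count
                elif code == "I":
                    nm += count
                    i += count
                elif code == "D":
                    nm += count
                    j += count
            assert rec.get_tag("NM") == nm
            assert rec.has_tag("MD")


def test_unmapped_and_secondary_pass_through(tmp_path, default_model):
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "c1", "LN": 100}]}
    ref = "ACGT" * 25
    with pysam.AlignmentFile(str(tmp_path / "in.bam"), "wb", header=header) as bam:
        a = pysam.AlignedSegment()
        a.query_name = "mapped"
        a.query_sequence = ref[:30]
        a.flag = 0
        a.reference_id = 0
        a.reference_start = 0
        a.cigarstring = "30M"
        a.mapping_quality = 60
        bam.write(a)
        b = pysam.AlignedSegment()
        b.query_name = "secondary"
        b.query_sequence = None
        b.flag = 256
        b.reference_id = 0
        b.reference_start = 10
        b.cigarstring = "20M"
        b.mapping_quality = 0
        bam.write(b)
        c = pysam.AlignedSegment()
        c.query_name = "unmapped"
        c.query_sequence = "ACGTACGT"
        c.flag = 4
        bam.write(c)
    write_fasta = __import__("npore.simulate", fromlist=["write_fasta"]).write_fasta
    write_fasta(str(tmp_path / "ref.fa"), "c1", ref)
    stats = realign_bam(str(tmp_path / "in.bam"), str(tmp_path / "ref.fa"),
                        default_model, str(tmp_path / "out.bam"))
    assert stats.realigned == 1
    assert stats.passthrough == 2
    with pysam.AlignmentFile(str(tmp_path / "out.bam")) as bam:
        names = [r.query_name for r in bam]
    assert names == ["mapped", "secondary", "unmapped"]


def test_soft_clips_preserved(tmp_path, default_model):
    ref = "GGCATTAGCATTACGATTAGCATCAGCT" * 3
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "c1", "LN": len(ref)}]}
    with pysam.AlignmentFile(str(tmp_path / "in.bam"), "wb", header=header) as bam:
        a = pysam.AlignedSegment()
        a.query_name = "clipped"
        a.query_sequence = "TTTT" + ref[10:40] + "GG"
        a.flag = 0
        a.reference_id = 0
        a.reference_start = 10
        a.cigarstring = "4S30M2S"
        a.mapping_quality = 60
        bam.write(a)
    from npore.simulate import write_fasta as wf

    wf(str(tmp_path / "ref.fa"), "c1", ref)
    realign_bam(str(tmp_path / "in.bam"), str(tmp_path / "ref.fa"),
                default_model, str(tmp_path / "out.bam"))
    with pysam.AlignmentFile(str(tmp_path / "out.bam")) as bam:
        rec = next(iter(bam))
    assert rec.cigarstring.startswith("4S")
    assert rec.cigarstring.endswith("2S")
    assert rec.reference_start == 10
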