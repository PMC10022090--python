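"""Penalty estimation: substitution matrix, affine fit, copy-number tensor."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npore.annotation import annotate_reference
from npore.model import (ConfusionCounts, PenaltyModel, count_confusions,
                         fit_affine, indel_penalty_curve, npolymer_penalties,
                         regularize_npolymer, substitution_penalties)


# ---------------------------------------------------------------------------
# substitution penalties

def test_substitution_uniform_row_gives_log4():
    C = np.full((4, 4), 1_000_000)
    P = substitution_penalties(C)
    assert np.allclose(P, math.log(4), atol=1e-5)


def test_substitution_direct_evaluation():
    C = np.zeros((4, 4))
    C[0] = (97, 1, 1, 1)
    P = substitution_penalties(C, eps=0.01)
    assert P[0, 0] == pytest.approx(-math.log(97.01 / 100.01))
    assert P[0, 1] == pytest.approx(-math.log(1.01 / 100.01))


def test_substitution_all_zero_row_is_free():
    P = substitution_penalties(np.zeros((4, 4)), eps=0.01)
    assert np.allclose(P, 0.0)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(0, 10_000), min_size=16, max_size=16))
def test_probability_rows_sum_to_one(counts):
    """exp(-P) rows sum to 1 up to the eps-induced slack (rows with data)."""
    C = np.array(counts, dtype=float).reshape(4, 4)
    P = substitution_penalties(C, eps=0.01)
    rows = np.exp(-P).sum(axis=1)
    totals = C.sum(axis=1)
    mask = totals > 0
    slack = 5 * 0.01 / totals[mask] + 1e-9
    assert (np.abs(rows[mask] - 1) <= slack).all()


def test_doubling_probability_shifts_penalty_by_log2():
    """-log p drops by exactly ln 2 when an event becomes twice as likely."""
    total = 1_000_000
    C1 = np.zeros((4, 4))
    C2 = np.zeros((4, 4))
    C1[0] = (total - 1000, 1000, 0, 0)
    C2[0] = (total - 2000, 2000, 0, 0)
    P1 = substitution_penalties(C1)
    P2 = substitution_penalties(C2)
    assert P1[0, 1] - P2[0, 1] == pytest.approx(math.log(2), abs=2e-3)


# ---------------------------------------------------------------------------
# affine gap fit

def test_affine_fit_exact_linear():
    pen = {g: 5.0 + (g - 1) * 1.0 for g in range(1, 8)}
    assert fit_affine(pen) == pytest.approx((5.0, 1.0))


def test_affine_defaults_with_warning():
    with pytest.warns(UserWarning):
        g_open, g_ext = fit_affine({3: 7.0})
    assert (g_open, g_ext) == (5.0, 1.0)


def test_three_base_gap_costs_seven_under_defaults():
    model = PenaltyModel.affine_only()
    assert model.gap_cost(3) == 7.0


def test_affine_fit_recovers_noisy_truth(rng):
    """Repeated noisy fits stay within 3 s.e. of the generating line."""
    g_opens, g_exts = [], []
    for _ in range(200):
        lens = np.arange(1, 9)
        pen = 4.0 + (lens - 1) * 1.5 + rng.normal(0, 0.3, size=len(lens))
        go, ge = fit_affine(dict(zip(lens, pen)))
        g_opens.append(go)
        g_exts.append(ge)
    assert abs(np.mean(g_opens) - 4.0) < 3 * np.std(g_opens) / math.sqrt(200)
    assert abs(np.mean(g_exts) - 1.5) < 3 * np.std(g_exts) / math.sqrt(200)


def test_indel_penalty_curve_scale():
    C = np.zeros(51)
    C[0] = 99_000
    C[1] = 1_000
    curve = indel_penalty_curve(C)
    assert curve[1] == pytest.approx(-math.log(1000.01 / 100_000.01))
    assert set(curve) == {1}


# ---------------------------------------------------------------------------
# copy-number tensor

def test_npolymer_hand_filled_row_matches_direct_formula():
    """A hand-filled 1x6x6 row reproduces the row-normalised -log values."""
    C = np.zeros((1, 6, 6))
    C[0, 3] = [1, 10, 60, 500, 50, 8]
    N = npolymer_penalties(C, eps=0.01, regularize=False)
    tot = C[0, 3].sum() + 0.01
    expect = [-math.log((c + 0.01) / tot) for c in C[0, 3]]
    assert np.allclose(N[0, 3], expect)


def test_regularization_enforces_both_families():
    rng = np.random.default_rng(7)
    N = rng.uniform(0.5, 8.0, size=(2, 12, 12))
    R = regularize_npolymer(N)
    for nn in range(2):
        for i in range(12):
            for sign in (1, -1):
                for k in range(1, 12):
                    j, j2 = i + sign * k, i + sign * (k + 1)
                    if 0 <= j2 < 12 and k >= 1:
                        assert R[nn, i, j] < R[nn, i, j2]  # shorter indels likelier
                    jo = (i + 1) + sign * k
                    if i + 1 < 12 and 0 <= j < 12 and 0 <= jo < 12:
                        assert R[nn, i + 1, jo] < R[nn, i, j]  # longer polymers likelier


def test_regularization_printed_direction_flag():
    rng = np.random.default_rng(7)
    N = rng.uniform(0.5, 8.0, size=(1, 10, 10))
    R = regularize_npolymer(N, printed_direction=True)
    for i in range(10):
        for sign in (1, -1):
            for k in range(1, 10):
                j, j2 = i + sign * k, i + sign * (k + 1)
                if 0 <= j2 < 10:
                    assert R[0, i, j] > R[0, i, j2]
                jo = (i + 1) + sign * k
                if i + 1 < 10 and 0 <= j < 10 and 0 <= jo < 10:
                    assert R[0, i + 1, jo] > R[0, i, j]


def test_regularization_never_lowers_penalties():
    rng = np.random.default_rng(3)
    N = rng.uniform(0.5, 8.0, size=(1, 10, 10))
    R = regularize_npolymer(N)
    assert (R >= N - 1e-12).all()


def test_eps_dominated_off_diagonals_equal():
    C = np.zeros((1, 8, 8))
    for i in range(8):
        C[0, i, i] = 1000
    N = npolymer_penalties(C, regularize=False)
    off = N[0, 4, [0, 1, 2, 3, 5, 6, 7]]
    assert np.allclose(off, off[0])


def test_default_model_satisfies_regularity_and_discussion_scale():
    """The parametric default keeps copy-number indels cheaper than affine."""
    m = PenaltyModel.default()
    assert m.n_cost(1, 10, 9) < m.gap_cost(1)
    assert m.n_cost(3, 5, 4) < m.gap_cost(3)
    # both monotonicity families on a probe slice
    for i in range(4, 20):
        assert m.n_cost(1, i, i - 1) < m.n_cost(1, i, i - 2)
        assert m.n_cost(1, i + 1, i) < m.n_cost(1, i, i - 1)


# ---------------------------------------------------------------------------
# confusion counting

def test_perfect_read_counts_only_matches():
    ref = "ACGTACGTACGTACGTACGT"
    ann = annotate_reference(ref)
    cc = count_confusions([(ref, ref, "20M")], ann)
    assert cc.C_P.trace() == 20
    assert cc.C_P.sum() == 20
    assert cc.C_I[1:].sum() == 0 and cc.C_D[1:].sum() == 0


def test_insertion_run_counts_once_at_its_length():
    ref = "ACGTAGCTAC"
    read = ref[:5] + "TTT" + ref[5:]
    ann = annotate_reference(ref)
    cc = count_confusions([(read, ref, "5M3I5M")], ann)
    assert cc.C_I[3] == 1
    assert cc.C_I[1] == 0


def test_homopolymer_deletion_feeds_copy_number_counts():
    ref = "GCAAAAATG"
    read = "GCAAAATG"
    ann = annotate_reference(ref)
    cc = count_confusions([(read, ref, "2M1D6M")], ann)
    assert cc.C_N[0, 5, 4] == 1


def test_partial_polymer_overlap_not_counted():
    ref = "GCAAAAATG"
    ann = annotate_reference(ref)
    cc = count_confusions([("CAAAA", "CAAAA", "5M", 1)], ann)  # no right flank
    assert cc.C_N[0, 5].sum() == 0


def test_counting_is_additive():
    ref = "GCAAAAATGGTTTTACGT"
    ann = annotate_reference(ref)
    a1 = [(ref, ref, "18M")]
    a2 = [("GCAAAATGGTTTTACGT", ref, "2M1D15M")]
    both = count_confusions(a1 + a2, ann)
    summed = count_confusions(a1, ann) + count_confusions(a2, ann)
    assert (both.C_P == summed.C_P).all()
    assert (both.C_I == summed.C_I).all()
    assert (both.C_D == summed.C_D).all()
    assert (both.C_N == summed.C_N).all()


def test_length_mismatch_raises():
    ann = annotate_reference("ACGT")
    with pytest.raises(ValueError, match="inconsistent"):
        count_confusions([("ACG", "ACGT", "4M")], ann)


def test_model_roundtrip_serialization(tmp_path, default_model):
    path = tmp_path / "model.json"
    default_model.save(str(path))
    loaded = PenaltyModel.load(str(path))
    assert np.allclose(loaded.P, default_model.P)
    assert np.allclose(loaded.N, default_model.N)
    assert loaded.G_open == default_model.G_open


def test_from_counts_produces_finite_nonnegative_model():
    ref = "GCAAAAATGGTTTTACGTAC"
    ann = annotate_reference(ref)
    cc = count_confusions([(ref, ref, "20M"),
                           ("GCAAAATGGTTTTACGTAC", ref, "2M1D17M")], ann)
    with pytest.warns(UserWarning):
        model = PenaltyModel.from_counts(cc)
    assert np.isfinite(model.P).all()
    assert (model.P >= 0).all()
    assert np.isfinite(model.N).all()
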