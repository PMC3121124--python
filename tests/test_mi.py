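"""Column statistics, position MI, shuffle null, and the domain score M_mn."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domcrf.alignments import pair_rows
from domcrf.alphabet import ALPHABET, N_JOINT, N_SYMBOLS
from domcrf.mi import (
    MIConfig,
    ShuffleDegenerateError,
    UndefinedFrequencyError,
    column_frequencies,
    compute_domain_mi,
    gap_mask,
    joint_frequencies,
    mi_position_pair,
    pseudocount,
    shuffle_null,
)

from conftest import make_alignment
from oracles import brute_force_mi, enumerate_shuffle_null


class TestPairing:
    def test_shared_organisms_paired_leftovers_dropped(self):
        a = make_alignment("Dm", [("X", "AA"), ("Y", "CC"), ("Z", "DD")])
        b = make_alignment("Dn", [("Y", "EE"), ("Z", "FF"), ("W", "GG")])
        pa = pair_rows(a, b)
        assert pa.M == 2
        assert pa.pairs == ((1, 0), (2, 1))  # a:Y-b:Y, a:Z-b:Z

    def test_self_pairing_is_identity(self):
        a = make_alignment("Dm", [("X", "AA"), ("X", "CC"), ("Y", "DD")])
        pa = pair_rows(a, a)
        assert pa.pairs == ((0, 0), (1, 1), (2, 2))
        assert pa.M == a.n_rows

    def test_unequal_copy_numbers_pair_in_file_order(self):
        # organism X: 2 rows in a, 3 in b -> exactly 2 pairs, file order
        a = make_alignment("Dm", [("X", "AA"), ("Y", "CC"), ("X", "DD")])
        b = make_alignment("Dn", [("X", "EE"), ("X", "FF"), ("Z", "GG"), ("X", "HH")])
        pa = pair_rows(a, b)
        assert pa.pairs == ((0, 0), (2, 1))

    def test_disjoint_organisms_give_empty_pairing(self):
        a = make_alignment("Dm", [("X", "AA")])
        b = make_alignment("Dn", [("Y", "CC")])
        assert pair_rows(a, b).M == 0


class TestFrequencies:
    def test_constant_column_no_pseudocount(self):
        a = make_alignment("Dm", [("O%d" % k, "A") for k in range(10)])
        pa = pair_rows(a, a)
        f = column_frequencies(pa, "a", 0, eta=0.0).freqs
        assert f[ALPHABET.index("A")] == 1.0
        assert f.sum() == pytest.approx(1.0)

    def test_constant_column_default_pseudocount(self):
        a = make_alignment("Dm", [("O%d" % k, "A") for k in range(10)])
        pa = pair_rows(a, a)
        f = column_frequencies(pa, "a", 0, eta=1.0).freqs
        assert f[ALPHABET.index("A")] == pytest.approx(11 / 21)
        others = np.delete(f, ALPHABET.index("A"))
        assert np.allclose(others, 1 / 42)
        assert np.all(f > 0)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_joint_counts_and_pseudocount(self):
        rows_a = [("O0", "A"), ("O1", "A"), ("O2", "C"), ("O3", "C")]
        rows_b = [("O0", "A"), ("O1", "C"), ("O2", "A"), ("O3", "C")]
        pa = pair_rows(make_alignment("Dm", rows_a), make_alignment("Dn", rows_b))
        f0 = joint_frequencies(pa, 0, 0, eta=0.0).freqs
        iA, iC = ALPHABET.index("A"), ALPHABET.index("C")
        for a_, b_ in itertools.product([iA, iC], repeat=2):
            assert f0[a_, b_] == pytest.approx(0.25)
        f1 = joint_frequencies(pa, 0, 0, eta=1.0).freqs
        assert f1[iA, iA] == pytest.approx((0.25 + 1 / 441) / 2)
        assert f1[iA, ALPHABET.index("D")] == pytest.approx((1 / 441) / 2)
        assert f1.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_pairing_raises(self):
        a = make_alignment("Dm", [("X", "AA")])
        b = make_alignment("Dn", [("Y", "CC")])
        pa = pair_rows(a, b)
        with pytest.raises(UndefinedFrequencyError):
            column_frequencies(pa, "a", 0)
        with pytest.raises(UndefinedFrequencyError):
            joint_frequencies(pa, 0, 0)

    def test_joint_marginalizes_to_column_frequencies(self):
        # exact consequence of the mixture pseudocount form, at any eta
        rows_a = [("O%d" % k, s) for k, s in enumerate("AACDEFGAC")]
        rows_b = [("O%d" % k, s) for k, s in enumerate("KKLMNPQKL")]
        pa = pair_rows(make_alignment("Dm", rows_a), make_alignment("Dn", rows_b))
        for eta in (0.0, 1.0):
            fij = joint_frequencies(pa, 0, 0, eta).freqs
            fi = column_frequencies(pa, "a", 0, eta).freqs
            assert np.allclose(fij.sum(axis=1), fi, atol=1e-14)


class TestPositionMI:
    def test_product_table_gives_zero(self, rng):
        fi = pseudocount(rng.dirichlet(np.ones(N_SYMBOLS)), 1.0, N_SYMBOLS)
        fj = pseudocount(rng.dirichlet(np.ones(N_SYMBOLS)), 1.0, N_SYMBOLS)
        assert mi_position_pair(fi, fj, np.outer(fi, fj)) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_permutation_coupling_is_ln_q(self, rng):
        q = N_SYMBOLS
        perm = rng.permutation(q)
        fij = np.zeros((q, q))
        fij[np.arange(q), perm] = 1.0 / q
        fi = np.full(q, 1.0 / q)
        # no pseudocount: zeros are excluded from the sum by the oracle and by
        # the convention 0 log 0 = 0; use a tiny floor for the implementation
        floor = 1e-30
        mi = mi_position_pair(fi, fi, np.maximum(fij, floor))
        assert mi == pytest.approx(np.log(q), abs=1e-9)

    def test_four_row_toy_is_independent(self):
        rows_a = [("O0", "A"), ("O1", "A"), ("O2", "C"), ("O3", "C")]
        rows_b = [("O0", "A"), ("O1", "C"), ("O2", "A"), ("O3", "C")]
        pa = pair_rows(make_alignment("Dm", rows_a), make_alignment("Dn", rows_b))
        fij = joint_frequencies(pa, 0, 0, eta=0.0).freqs
        fi = column_frequencies(pa, "a", 0, eta=0.0).freqs
        fj = column_frequencies(pa, "b", 0, eta=0.0).freqs
        mi = mi_position_pair(
            np.maximum(fi, 1e-30), np.maximum(fj, 1e-30), np.maximum(fij, 1e-30)
        )
        assert mi == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(25):
            raw = rng.dirichlet(np.ones(N_JOINT)).reshape(N_SYMBOLS, N_SYMBOLS)
            fij = pseudocount(raw, 1.0, N_JOINT)
            fi, fj = fij.sum(axis=1), fij.sum(axis=0)
            assert mi_position_pair(fi, fj, fij) == pytest.approx(
                brute_force_mi(fij, fi, fj), abs=1e-10
            )

    def test_rejects_nonpositive_frequencies(self):
        fi = np.full(N_SYMBOLS, 1 / N_SYMBOLS)
        fij = np.zeros((N_SYMBOLS, N_SYMBOLS))
        with pytest.raises(ValueError):
            mi_position_pair(fi, fi, fij)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_mi_bounds_and_eta_contraction(self, seed):
        # 0 <= MI <= ln 21, and mixing toward the product-uniform shrinks MI
        r = np.random.default_rng(seed)
        raw = r.dirichlet(np.full(N_JOINT, 0.05)).reshape(N_SYMBOLS, N_SYMBOLS)
        last = np.inf
        for eta in (0.0, 0.5, 1.0, 2.0):
            fij = pseudocount(np.maximum(raw, 1e-30), eta, N_JOINT)
            fij /= fij.sum()
            fi, fj = fij.sum(axis=1), fij.sum(axis=0)
            mi = mi_position_pair(fi, fj, fij)
            assert -1e-12 <= mi <= np.log(N_SYMBOLS) + 1e-9
            assert mi <= last + 1e-9
            last = mi


class TestGapMask:
    def _pa(self, seqs_a):
        a = make_alignment("Dm", [("O%d" % k, s) for k, s in enumerate(seqs_a)])
        b = make_alignment("Dn", [("O%d" % k, "A") for k in range(len(seqs_a))])
        return a, pair_rows(a, b)

    def test_strictly_above_threshold_masked(self):
        seqs = ["-"] * 3 + ["A"] * 7  # 30% gaps
        a, pa = self._pa(seqs)
        assert gap_mask(a, 0.20, pa)[0]

    def test_exactly_at_threshold_kept(self):
        seqs = ["-"] * 2 + ["A"] * 8  # exactly 20%
        a, pa = self._pa(seqs)
        assert not gap_mask(a, 0.20, pa)[0]

    def test_threshold_one_masks_nothing(self):
        a, pa = self._pa(["-"] * 10)
        assert not gap_mask(a, 1.0, pa).any()

    def test_computed_over_paired_rows_only(self):
        # a's unpaired row is all gaps; paired rows are gap-free
        a = make_alignment("Dm", [("X", "-"), ("Y", "A"), ("Z", "C")])
        b = make_alignment("Dn", [("Y", "T"), ("Z", "T")])
        pa = pair_rows(a, b)
        assert not gap_mask(a, 0.20, pa)[0]


def _constant_pairing(M=4):
    a = make_alignment("Dm", [("O%d" % k, s) for k, s in enumerate("ACDE"[:M])])
    b = make_alignment("Dn", [("O%d" % k, "T") for k in range(M)])
    return pair_rows(a, b)


class TestShuffleNull:
    def test_constant_partner_column_nullifies_mi(self):
        pa = _constant_pairing()
        null = shuffle_null(pa, 0, 0, eta=1.0, n_shuffles=10, seed=0)
        fij = joint_frequencies(pa, 0, 0, 1.0)
        fi = column_frequencies(pa, "a", 0, 1.0)
        fj = column_frequencies(pa, "b", 0, 1.0)
        raw = mi_position_pair(fi, fj, fij)
        assert null == pytest.approx(raw, abs=1e-12)

    def test_degenerate_pairing_raises(self):
        a = make_alignment("Dm", [("X", "A")])
        pa = pair_rows(a, a)
        with pytest.raises(ShuffleDegenerateError):
            shuffle_null(pa, 0, 0, n_shuffles=10, seed=0)

    def test_deterministic_given_seed(self, toy_pairing):
        n1 = shuffle_null(toy_pairing, 0, 1, n_shuffles=50, seed=11)
        n2 = shuffle_null(toy_pairing, 0, 1, n_shuffles=50, seed=11)
        assert n1 == n2

    def test_monte_carlo_matches_full_enumeration_small_m(self):
        # M = 3: the null over all 3! pairings is exactly enumerable
        a = make_alignment("Dm", [("O0", "A"), ("O1", "C"), ("O2", "D")])
        b = make_alignment("Dn", [("O0", "K"), ("O1", "L"), ("O2", "M")])
        pa = pair_rows(a, b)
        eta = 1.0

        def mi_of(col_a, col_b):
            counts = np.zeros((N_SYMBOLS, N_SYMBOLS))
            for x, y in zip(col_a, col_b):
                counts[ALPHABET.index(x), ALPHABET.index(y)] += 1
            fij = pseudocount(counts / len(col_a), eta, N_JOINT)
            return brute_force_mi(fij, fij.sum(axis=1), fij.sum(axis=0))

        exact = enumerate_shuffle_null("ACD", "KLM", mi_of)
        mc_vals = [
            shuffle_null(pa, 0, 0, eta=eta, n_shuffles=400, seed=s) for s in range(5)
        ]
        se = np.std(mc_vals, ddof=1) / np.sqrt(len(mc_vals))
        assert abs(np.mean(mc_vals) - exact) < max(3 * se, 1e-3)


def _coevolving_pair(M=40, seed=5):
    """Perfect 4-symbol coupling in column 0; independent column elsewhere."""
    r = np.random.default_rng(seed)
    syms = "ACDE"
    rows_a, rows_b = [], []
    for k in range(M):
        s = syms[r.integers(4)]
        rows_a.append(("O%d" % k, s + "FGHI"[r.integers(4)]))
        rows_b.append(("O%d" % k, s + "KLMN"[r.integers(4)]))
    return make_alignment("Dm", rows_a), make_alignment("Dn", rows_b)


class TestDomainMI:
    def test_coevolving_column_found_near_ln4_minus_null(self):
        a, b = _coevolving_pair()
        cfg = MIConfig(eta=0.0, n_shuffles=400, seed=3)
        score = compute_domain_mi(a, b, cfg)
        pa = pair_rows(a, b)
        null = shuffle_null(pa, 0, 0, eta=0.0, n_shuffles=400, seed=99)
        fij = joint_frequencies(pa, 0, 0, 0.0).freqs
        fi = column_frequencies(pa, "a", 0, 0.0).freqs
        fj = column_frequencies(pa, "b", 0, 0.0).freqs
        raw = mi_position_pair(
            np.maximum(fi, 1e-30), np.maximum(fj, 1e-30), np.maximum(fij, 1e-30)
        )
        assert score.best_positions == (0, 0)
        # raw MI of the perfectly coupled pair is near ln 4 (finite-M noise)
        assert raw == pytest.approx(np.log(4), abs=0.3)
        assert score.m_mn == pytest.approx(raw - null, abs=0.05)

    def test_symmetry_bit_for_bit(self):
        a, b = _coevolving_pair()
        cfg = MIConfig(seed=17)
        assert compute_domain_mi(a, b, cfg) == compute_domain_mi(b, a, cfg)

    def test_same_seed_identical_rerun(self):
        a, b = _coevolving_pair()
        cfg = MIConfig(seed=23)
        s1 = compute_domain_mi(a, b, cfg)
        s2 = compute_domain_mi(a, b, cfg)
        assert s1.m_mn == s2.m_mn

    def test_pruned_scan_equals_exhaustive_scan(self):
        a, b = _coevolving_pair(M=30, seed=9)
        cfg = MIConfig(seed=4)
        assert compute_domain_mi(a, b, cfg) == compute_domain_mi(a, b, cfg, exhaustive=True)

    def test_single_column_constant_self_pair_unavailable(self):
        # self pair of a 1-column alignment: only the diagonal exists
        a = make_alignment("Dm", [("O%d" % k, "A") for k in range(5)])
        score = compute_domain_mi(a, a, MIConfig(seed=0))
        assert not score.available

    def test_constant_single_columns_give_zero(self):
        a = make_alignment("Dm", [("O%d" % k, "A") for k in range(5)])
        b = make_alignment("Dn", [("O%d" % k, "C") for k in range(5)])
        score = compute_domain_mi(a, b, MIConfig(seed=0))
        assert score.m_mn == pytest.approx(0.0, abs=1e-12)

    def test_too_few_pairs_unavailable(self):
        a = make_alignment("Dm", [("X", "AC")])
        b = make_alignment("Dn", [("X", "DE")])
        assert not compute_domain_mi(a, b, MIConfig(seed=0)).available

    def test_all_columns_gappy_unavailable(self):
        a = make_alignment("Dm", [("O%d" % k, "--") for k in range(6)])
        b = make_alignment("Dn", [("O%d" % k, "AC") for k in range(6)])
        assert not compute_domain_mi(a, b, MIConfig(seed=0)).available
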