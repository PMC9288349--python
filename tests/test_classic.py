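"""Classic expanded (2,2)-VCS and (2,2)-EVCS."""

from itertools import permutations, product

import numpy as np
import pytest
from scipy import stats

from vcshare.classic import (
    BLACK,
    WHITE,
    all_patterns,
    encrypt_evcs_expanded,
    encrypt_vcs,
    evcs_basis,
    evcs_row_count,
    evcs_stack_count,
    permute_columns,
    vcs_basis,
)
from vcshare.efvcs import valid_pairs
from vcshare.halftone import block_counts
from vcshare.shares import stack


def _and_count(m):
    return 4 - int((m[0] & m[1]).sum())


class TestBases:
    def test_vcs_basis_invariants(self):
        s0, s1 = vcs_basis()
        for m in (s0, s1):
            assert ((m == 0).sum(axis=1) == 2).all()  # 2 black per row
        assert np.array_equal(s0[0], s0[1])  # white: identical rows
        assert _and_count(s1) == 4  # black: complementary rows stack all-black
        assert _and_count(s0) == 2

    def test_evcs_basis_all_eight_combinations(self):
        for s, c1, c2 in product((BLACK, WHITE), repeat=3):
            m = evcs_basis(s, c1, c2)
            assert (m[0] == 0).sum() == evcs_row_count(c1)
            assert (m[1] == 0).sum() == evcs_row_count(c2)
            assert _and_count(m) == evcs_stack_count(s)

    def test_canonical_black_cover_matrices(self):
        np.testing.assert_array_equal(
            evcs_basis(BLACK, BLACK, BLACK), [[0, 1, 0, 0], [1, 0, 0, 0]]
        )
        np.testing.assert_array_equal(
            evcs_basis(WHITE, BLACK, BLACK), [[0, 1, 0, 0], [0, 1, 0, 0]]
        )

    def test_white_secret_white_covers_has_disjoint_whites(self):
        m = evcs_basis(BLACK, WHITE, WHITE)
        whites0 = set(np.flatnonzero(m[0]))
        whites1 = set(np.flatnonzero(m[1]))
        assert whites0.isdisjoint(whites1)  # stack must be all-black

    def test_column_permutations_match_valid_pair_family(self):
        """Permuting basis columns reaches exactly the valid-pair set."""
        for s, c1, c2 in product((BLACK, WHITE), repeat=3):
            m = evcs_basis(s, c1, c2)
            perms = {
                (tuple(m[0, p]), tuple(m[1, p]))
                for p in map(list, permutations(range(4)))
            }
            expected = set(
                valid_pairs(evcs_stack_count(s), evcs_row_count(c1), evcs_row_count(c2))
            )
            assert perms == expected


class TestPermuteColumns:
    def test_row_sums_invariant(self, rng):
        m = evcs_basis(BLACK, WHITE, BLACK)
        for _ in range(20):
            p = permute_columns(m, rng)
            np.testing.assert_array_equal(p.sum(axis=1), m.sum(axis=1))

    def test_wbb_has_four_distinct_permutations(self):
        m = evcs_basis(WHITE, BLACK, BLACK)
        distinct = {
            tuple(map(tuple, m[:, p])) for p in map(list, permutations(range(4)))
        }
        assert len(distinct) == 4  # three identical columns collapse 4! to 4


class TestEncryptVcs:
    def test_black_secret_stacks_all_black(self, rng):
        secret = np.zeros((2, 2), dtype=np.uint8)
        rec = stack(encrypt_vcs(secret, rng))
        assert (rec == 0).all()

    def test_white_secret_stacks_half_black(self, rng):
        secret = np.ones((2, 2), dtype=np.uint8)
        rec = stack(encrypt_vcs(secret, rng))
        assert (block_counts(rec, (2, 2)) == 2).all()

    def test_share_blocks_always_two_black(self, rng):
        secret = rng.integers(0, 2, (8, 8)).astype(np.uint8)
        ss = encrypt_vcs(secret, rng)
        for sh in ss.shares:
            assert (block_counts(sh, (2, 2)) == 2).all()
        assert ss.shares[0].shape == (16, 16)


class TestEncryptEvcs:
    def test_recovery_and_cover_fidelity(self, rng):
        secret = rng.integers(0, 2, (16, 16)).astype(np.uint8)
        c1 = rng.integers(0, 2, (16, 16)).astype(np.uint8)
        c2 = rng.integers(0, 2, (16, 16)).astype(np.uint8)
        ss = encrypt_evcs_expanded(secret, c1, c2, rng)
        rec = stack(ss)
        np.testing.assert_array_equal(
            block_counts(rec, (2, 2)), np.where(secret == BLACK, 4, 3)
        )
        np.testing.assert_array_equal(
            block_counts(ss.shares[0], (2, 2)), np.where(c1 == BLACK, 3, 2)
        )
        np.testing.assert_array_equal(
            block_counts(ss.shares[1], (2, 2)), np.where(c2 == BLACK, 3, 2)
        )

    def test_expansion_is_four(self, rng):
        secret = rng.integers(0, 2, (64, 64)).astype(np.uint8)
        ss = encrypt_evcs_expanded(secret, secret, secret, rng)
        assert ss.shares[0].size / secret.size == 4.0

    def test_dimension_mismatch_rejected(self, rng):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 6), dtype=np.uint8)
        with pytest.raises(ValueError, match="dimensions"):
            encrypt_evcs_expanded(a, a, b, rng)


class TestStack:
    def test_worked_examples(self):
        c1 = np.array([[0, 1], [0, 0]], dtype=np.uint8)
        np.testing.assert_array_equal(
            stack([c1, np.array([[1, 0], [0, 0]], dtype=np.uint8)]), [[0, 0], [0, 0]]
        )
        np.testing.assert_array_equal(stack([c1, c1.copy()]), c1)

    def test_identity_and_idempotence(self, rng):
        x = rng.integers(0, 2, (6, 6)).astype(np.uint8)
        np.testing.assert_array_equal(stack([x, x]), x)
        np.testing.assert_array_equal(stack([x, np.ones_like(x)]), x)


class TestSecurityMarginals:
    def test_single_share_distribution_ignores_secret(self):
        """Share-1 pattern frequencies on black vs white secrets are
        statistically indistinguishable (same covers)."""
        rng = np.random.default_rng(99)
        shape = (100, 100)  # 10,000 pixels
        covers = (np.zeros(shape, dtype=np.uint8), np.zeros(shape, dtype=np.uint8))
        tables = []
        pats = all_patterns(4, 3)  # black cover -> 3-black tiles
        index = {p: i for i, p in enumerate(pats)}
        for secret_val in (0, 1):
            secret = np.full(shape, secret_val, dtype=np.uint8)
            ss = encrypt_evcs_expanded(secret, *covers, rng)
            sh = ss.shares[0]
            blocks = sh.reshape(shape[0], 2, shape[1], 2).swapaxes(1, 2).reshape(-1, 4)
            counts = np.zeros(len(pats), dtype=np.int64)
            for row in blocks:
                counts[index[tuple(int(v) for v in row)]] += 1
            tables.append(counts)
        _, p, _, _ = stats.chi2_contingency(np.array(tables))
        assert p > 0.01
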