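"""Per-column divergence statistic, color binning and conservation calls."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foldcompare.conservation import (
    PositionProfile,
    SimilarityGroups,
    assign_colors,
    classify_conservation,
    column_rms_divergence,
    pairwise_identity,
)
from foldcompare.multalign import MultipleAlignment, column_coordinates
from foldcompare.structio import CaTrace, RigidTransform

from conftest import random_rigid


def msa_from_columns(letter_rows, coord_rows=None):
    """Build a gap-free MultipleAlignment from per-member sequences.

    ``letter_rows`` is a list of equal-length strings ('-' marks a gap);
    optional ``coord_rows`` supplies per-member (ncols, 3) coordinates.
    """
    ncols = len(letter_rows[0])
    members, columns = [], []
    col_table = np.full((ncols, len(letter_rows)), -1, int)
    for m, row in enumerate(letter_rows):
        seq = row.replace("-", "")
        k = 0
        coords = []
        for c, letter in enumerate(row):
            if letter != "-":
                col_table[c, m] = k
                if coord_rows is not None:
                    coords.append(coord_rows[m][c])
                else:
                    coords.append([float(c), float(m), 0.0])
                k += 1
        members.append(
            CaTrace(f"m{m+1}", "", [(i + 1, "") for i in range(k)], seq, np.array(coords))
        )
    transforms = [RigidTransform.identity() for _ in members]
    return MultipleAlignment(members, col_table, transforms)


class TestColumnRms:
    def test_identical_coordinates_give_zero(self):
        rows = ["AAA", "AAA", "AAA"]
        coords = [np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])] * 3
        msa = msa_from_columns(rows, coords)
        prof = column_rms_divergence(msa)
        np.testing.assert_allclose(prof.rms, 0.0, atol=1e-12)

    def test_two_members_equal_the_single_distance(self):
        coords = [
            np.array([[0.0, 0, 0], [0, 0, 0]]),
            np.array([[3.0, 4, 0], [0, 0, 7]]),
        ]
        msa = msa_from_columns(["AA", "AA"], coords)
        prof = column_rms_divergence(msa)
        np.testing.assert_allclose(prof.rms, [5.0, 7.0], atol=1e-12)

    def test_three_members_hand_enumerated(self):
        # pairwise distances 1, 2, 2 -> rms = sqrt((1+4+4)/3) = sqrt(3)
        p1 = [0.0, 0.0, 0.0]
        p2 = [1.0, 0.0, 0.0]
        p3 = [0.5, np.sqrt(4 - 0.25), 0.0]
        coords = [np.array([p]) for p in (p1, p2, p3)]
        msa = msa_from_columns(["A", "A", "A"], coords)
        prof = column_rms_divergence(msa)
        assert prof.rms[0] == pytest.approx(np.sqrt(3.0), abs=1e-12)

    def test_matches_bruteforce_double_loop(self, family_msa):
        prof = column_rms_divergence(family_msa)
        for c in range(family_msa.n_columns):
            pts = column_coordinates(family_msa, c)
            if len(pts) < 2:
                assert np.isnan(prof.rms[c])
                continue
            acc = [
                np.sum((pts[i] - pts[j]) ** 2)
                for i in range(len(pts))
                for j in range(i + 1, len(pts))
            ]
            expected = np.sqrt(np.mean(acc))
            assert prof.rms[c] == pytest.approx(expected, abs=1e-12)

    def test_rigid_motion_invariance(self, family_msa):
        prof = column_rms_divergence(family_msa)
        rng = np.random.default_rng(5)
        R, t = random_rigid(rng)
        extra = RigidTransform(R, t)
        moved = MultipleAlignment(
            family_msa.members,
            family_msa.columns,
            [extra.compose(tr) for tr in family_msa.transforms],
        )
        prof2 = column_rms_divergence(moved)
        np.testing.assert_allclose(prof.rms, prof2.rms, atol=1e-9)

    def test_mean_mode_bounded_by_quadratic(self, family_msa):
        q = column_rms_divergence(family_msa, "quadratic").rms
        m = column_rms_divergence(family_msa, "mean").rms
        ok = np.isfinite(q)
        assert np.all(m[ok] <= q[ok] + 1e-12)

    def test_undefined_for_single_member_columns(self):
        msa = msa_from_columns(["AB", "A-"])
        prof = column_rms_divergence(msa)
        assert np.isfinite(prof.rms[0]) and np.isnan(prof.rms[1])


class TestColors:
    def test_constant_rms_single_bin(self):
        msa = msa_from_columns(["AAAA", "AAAA"])
        prof = PositionProfile(rms=np.full(4, 1.5), n_members=np.full(4, 2))
        bins = assign_colors(prof, msa, mode="linear")
        assert set(bins) == {0}

    def test_linear_binning_monotone(self):
        msa = msa_from_columns(["A" * 20, "A" * 20])
        prof = PositionProfile(rms=np.linspace(0, 5, 20), n_members=np.full(20, 2))
        bins = assign_colors(prof, msa, palette_size=7, mode="linear")
        assert np.all(np.diff(bins) >= 0)
        assert bins.max() == 6 and bins.min() == 0

    def test_quantile_bins_balanced_within_one(self):
        rng = np.random.default_rng(8)
        n = 100
        msa = msa_from_columns(["A" * n, "A" * n])
        prof = PositionProfile(rms=rng.uniform(0, 9, n), n_members=np.full(n, 2))
        bins = assign_colors(prof, msa, palette_size=10, mode="quantile")
        occ = np.bincount(bins, minlength=10)
        assert occ.max() - occ.min() <= 1

    def test_gapped_columns_grey_by_policy(self):
        msa = msa_from_columns(["ABC", "A-C", "AB-"])
        prof = column_rms_divergence(msa)
        any_gap = assign_colors(prof, msa, grey_policy="any_gap")
        assert list(any_gap[1:]) == [-1, -1] and any_gap[0] >= 0
        min_members = assign_colors(prof, msa, grey_policy="min_members")
        assert np.all(min_members >= 0)  # every column still has >= 2 members

    def test_bad_palette_refused(self):
        prof = PositionProfile(rms=np.ones(3), n_members=np.full(3, 2))
        with pytest.raises(ValueError):
            assign_colors(prof, None, palette_size=1, grey_policy="min_members")


class TestConservation:
    def test_class_calls(self):
        msa = msa_from_columns(["VVKD", "VIK-", "VLRE"])
        classes, census = classify_conservation(msa)
        assert classes == ["identical", "similar", "similar", "gapped"]
        assert census["identical"] == 1 and census["similar"] == 2
        assert census["similar_or_identical"] == 3

    def test_census_partitions_columns(self, family_msa):
        classes, census = classify_conservation(family_msa)
        n = sum(census[k] for k in ("identical", "similar", "variable", "gapped"))
        assert n == family_msa.n_columns

    def test_scope_restriction(self):
        msa = msa_from_columns(["VD", "VD", "KE"])
        full, _ = classify_conservation(msa)
        assert full == ["variable", "similar"]  # D/E share the acidic group
        sub, _ = classify_conservation(msa, scope=[0, 1])
        assert sub == ["identical", "identical"]
        with pytest.raises(ValueError):
            classify_conservation(msa, scope=[])

    def test_similarity_partition_validated(self):
        with pytest.raises(ValueError):
            SimilarityGroups(groups=(("a", frozenset("AV")), ("b", frozenset("VL"))))

    @given(st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_identical_implies_similar_for_any_column(self, seed):
        rng = np.random.default_rng(seed)
        letters = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 4))
        msa = msa_from_columns([letters, letters, letters])
        classes, _ = classify_conservation(msa)
        assert all(c == "identical" for c in classes)


class TestPairwiseIdentity:
    def test_self_pair_is_unity(self):
        msa = msa_from_columns(["VKDLE", "VKDLE"])
        assert pairwise_identity(msa, (0, 1)) == (1.0, 1.0)

    def test_counting_example(self):
        # 10 aligned columns: 5 identical, 3 more in-group, 2 cross-group
        a = "VKDEG" + "LRE" + "AD"
        b = "VKDEG" + "IKD" + "DA"
        msa = msa_from_columns([a, b])
        ident, simil = pairwise_identity(msa, (0, 1))
        assert ident == pytest.approx(0.5)
        assert simil == pytest.approx(0.8)

    def test_no_shared_columns_refused(self):
        msa = msa_from_columns(["A-", "-A"])
        from foldcompare.errors import AlignmentError

        with pytest.raises(AlignmentError):
            pairwise_identity(msa, (0, 1))
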