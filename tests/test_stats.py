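"""PERMANOVA, axis partitioning, Wilcoxon, MDS, KDE, normality."""

import itertools

import numpy as np
import pytest

import isopoint as ip
from isopoint import stats as st
from isopoint.synthetic import make_cohort

from conftest import random_rigid


class TestPermanova:
    def test_toy_groups_exhaustive_enumeration(self):
        """Two tight 1-D pairs far apart: only the 2 faithful splits of the
        6 possible reach the observed F, so the exhaustive p is 1/3."""
        r = ip.permanova([[0.0], [0.1]], [[10.0], [10.1]], exhaustive=True)
        assert r.p_value == pytest.approx(1 / 3)
        # hand computation of pseudo-F for these 4 points
        # SS_total = 99.9933..., SS_within = 0.01, F = (SS_b/1)/(SS_w/2)
        d2 = {}
        pts = [0.0, 0.1, 10.0, 10.1]
        ss_total = sum((a - b) ** 2 for a, b in itertools.combinations(pts, 2)) / 4
        ss_within = (0.1**2) / 2 + (0.1**2) / 2
        f_hand = (ss_total - ss_within) / (ss_within / 2)
        assert r.pseudo_f == pytest.approx(f_hand, rel=1e-12)

    def test_matches_scikit_bio(self, rng):
        """Independent cross-check against the reference implementation."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        A = rng.normal(0, 1, (12, 3))
        B = rng.normal(0.8, 1, (15, 3))
        r = ip.permanova(A, B, n_perm=999, seed=5)
        X = np.vstack([A, B])
        dm = DistanceMatrix(np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1)))
        ref = sk_permanova(dm, ["a"] * 12 + ["b"] * 15, permutations=999)
        assert r.pseudo_f == pytest.approx(float(ref["test statistic"]), rel=1e-12)
        # both p-values come from 999 random permutations; they agree loosely
        assert abs(r.p_value - float(ref["p-value"])) < 0.05

    def test_translation_invariance(self, rng):
        A = rng.normal(size=(8, 3))
        B = rng.normal(size=(9, 3))
        shift = np.array([5.0, -3.0, 11.0])
        r0 = ip.permanova(A, B, n_perm=99, seed=0)
        r1 = ip.permanova(A + shift, B + shift, n_perm=99, seed=0)
        assert r0.pseudo_f == pytest.approx(r1.pseudo_f, rel=1e-12)
        assert r0.p_value == r1.p_value

    def test_reproducible_given_seed(self, rng):
        A = rng.normal(size=(10, 3))
        B = rng.normal(size=(10, 3))
        p1 = ip.permanova(A, B, n_perm=199, seed=77).p_value
        p2 = ip.permanova(A, B, n_perm=199, seed=77).p_value
        assert p1 == p2

    def test_type_one_error_near_alpha(self):
        """Independent identically distributed groups are rejected at ~alpha."""
        rej = 0
        n = 200
        for s in range(n):
            tb = make_cohort(n_subjects=20, delta=(0, 0, 0), seed=s, paired=False)
            r = ip.permanova(
                tb[["Sx", "Sy", "Sz"]].to_numpy(),
                tb[["Ix", "Iy", "Iz"]].to_numpy(),
                n_perm=199,
                seed=50_000 + s,
            )
            rej += r.p_value <= 0.05
        assert 0.02 <= rej / n <= 0.09

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            ip.permanova([[0.0]], [[1.0], [2.0]])


class TestAxisContribution:
    def test_printed_cohort_means_give_z_share(self):
        """The proximal-distal axis carries 95.1% of the S->I separation
        for the published cohort mean coordinates."""
        shares = ip.axis_contribution([39.15, -1.29, 9.32], [38.77, -1.48, 11.20])
        assert round(float(shares[2]) * 1000) / 10 == 95.1
        # full triple: 0.1444/3.7149, 0.0361/3.7149, 3.5344/3.7149
        assert shares == pytest.approx(
            np.array([0.1444, 0.0361, 3.5344]) / 3.7149, abs=1e-4
        )

    def test_pure_z_shift(self):
        assert ip.axis_contribution((1, 2, 3), (1, 2, 5)) == pytest.approx([0, 0, 1])

    def test_fractions_sum_to_one(self, rng):
        a, b = rng.normal(size=(2, 3))
        shares = ip.axis_contribution(a, b)
        assert np.all(shares >= 0)
        assert shares.sum() == pytest.approx(1.0, abs=1e-12)

    def test_identical_means_raise(self):
        with pytest.raises(ValueError):
            ip.axis_contribution((1, 2, 3), (1, 2, 3))


def _wilcoxon_brute(diffs):
    """Literal 2^n sign enumeration of the W+ null, mid-ranked ties."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in
         itertools.product([False, True], repeat=n)]
    )
    p_low = np.mean(ws <= w_obs + 1e-9)
    p_high = np.mean(ws >= w_obs - 1e-9)
    return w_obs, min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_three_positive_diffs(self):
        w, p = ip.wilcoxon_signed_rank([1, 2, 3])
        assert w == 6.0
        assert p == pytest.approx(0.25)

    def test_antisymmetric_pair_null_centre(self):
        w, p = ip.wilcoxon_signed_rank([-1, 1])
        assert p == 1.0

    def test_exact_matches_brute_enumeration(self, rng):
        """DP rank-sum counting equals literal 2^n enumeration, n <= 12,
        including ties and zeros."""
        for _ in range(100):
            n = rng.integers(2, 13)
            d = np.round(rng.normal(0.3, 1.0, n), 1)  # rounding makes ties
            if np.all(d == 0):
                continue
            w1, p1 = ip.wilcoxon_signed_rank(d)
            w2, p2 = _wilcoxon_brute(d)
            assert w1 == pytest.approx(w2)
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_exact_and_normal_agree_at_switchover(self, rng):
        """Exact and approximate p within 0.01 around n = 30."""
        for _ in range(30):
            d = rng.normal(0.4, 1.0, 30)
            _, p_exact = ip.wilcoxon_signed_rank(d, exact_max_n=30)
            _, p_norm = ip.wilcoxon_signed_rank(d, exact_max_n=0)
            assert abs(p_exact - p_norm) < 0.01

    def test_matches_scipy_on_tie_free_data(self, rng):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        for _ in range(20):
            d = rng.normal(0.5, 1.0, 12)
            _, p = ip.wilcoxon_signed_rank(d)
            ref = scipy_wilcoxon(d, method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            ip.wilcoxon_signed_rank([0.0, 0.0])


class TestMds:
    def test_planar_points_embed_exactly(self, rng):
        pts2 = rng.normal(size=(15, 2))
        rows = np.column_stack([pts2, np.zeros(15)])
        emb = ip.mds_embedding(rows, dims=2)
        d0 = np.linalg.norm(rows[:, None] - rows[None], axis=2)
        d1 = np.linalg.norm(emb[:, None] - emb[None], axis=2)
        assert np.abs(d0 - d1).max() < 1e-9

    def test_equilateral_triangle(self):
        rows = [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]]
        emb = ip.mds_embedding(rows, dims=2)
        d = np.linalg.norm(emb[:, None] - emb[None], axis=2)
        off = d[np.triu_indices(3, 1)]
        assert np.allclose(off, 1.0, atol=1e-9)

    def test_stress_nonincreasing_in_dims(self, rng):
        rows = rng.normal(size=(20, 3))
        d0 = np.linalg.norm(rows[:, None] - rows[None], axis=2)

        def stress(dims):
            emb = ip.mds_embedding(rows, dims=dims)
            d1 = np.linalg.norm(emb[:, None] - emb[None], axis=2)
            return np.sqrt(((d0 - d1) ** 2).sum())

        s1, s2, s3 = stress(1), stress(2), stress(3)
        assert s1 >= s2 - 1e-9 >= s3 - 2e-9
        assert s3 < 1e-6  # full dimension embeds exactly

    def test_too_few_rows_raise(self):
        with pytest.raises(ValueError):
            ip.mds_embedding([[0, 0, 0], [1, 1, 1]], dims=2)


class TestKde:
    def test_standard_normal_density_at_zero(self, rng):
        x = rng.normal(size=10_000)
        grid, dens = ip.kde_1d(x)
        at0 = dens[np.argmin(np.abs(grid))]
        assert abs(at0 - 0.3989) / 0.3989 < 0.15

    def test_nonnegative_and_normalized(self, rng):
        x = rng.normal(2.0, 3.0, 500)
        grid, dens = ip.kde_1d(x)
        assert np.all(dens >= 0)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_fixed_bandwidth_symmetric_unimodal(self):
        grid, dens = ip.kde_1d([3.0, 3.0 + 1e-9], bandwidth=0.5)
        peak = grid[np.argmax(dens)]
        assert peak == pytest.approx(3.0, abs=0.02)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            ip.kde_1d([1.0, 1.0])


class TestNormalityCheck:
    def test_uniform_sample_rejected_often(self, rng):
        rejected = sum(
            ip.normality_check(rng.uniform(size=100))[1] < 0.05 for _ in range(200)
        )
        assert rejected >= 180

    def test_normal_sample_type_one_rate(self, rng):
        rejected = sum(
            ip.normality_check(rng.normal(size=100))[1] < 0.05 for _ in range(200)
        )
        assert 0.02 * 200 <= rejected <= 0.08 * 200

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            ip.normality_check([2.0] * 10)


class TestCohortSummary:
    def test_planted_shift_recovered(self):
        tb = make_cohort(n_subjects=58, delta=(0, 0, 1.88), sigma=(0.3, 0.2, 0.5), seed=11)
        out = ip.cohort_summary(tb, n_perm=199, seed=3)
        assert out["I_Z_mean"] - out["S_Z_mean"] == pytest.approx(1.88, abs=0.4)
        assert out["axis_share"]["Z"] > 0.9
        assert out["p_Z"] < 0.01

    def test_pure_z_shift_dominates_axis_share(self):
        hits = 0
        for s in range(50):
            tb = make_cohort(n_subjects=58, delta=(0, 0, 2.0), sigma=(0.3, 0.2, 0.5),
                             seed=1000 + s)
            S = tb[["Sx", "Sy", "Sz"]].to_numpy().mean(axis=0)
            I = tb[["Ix", "Iy", "Iz"]].to_numpy().mean(axis=0)
            hits += ip.axis_contribution(S, I)[2] > 0.9
        assert hits >= 47
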