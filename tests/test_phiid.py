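"""Unit and property tests for the Gaussian PhiID core."""

import itertools

import numpy as np
import pytest

from synred.phiid import (
    ATOM_NAMES,
    DegenerateInputError,
    LaggedGaussianModel,
    double_redundancy_mmi,
    gaussian_mi,
    lagged_covariance,
    pairwise_phiid,
    phiid_decompose,
)

from conftest import ar1_series, random_pd_cov


# --------------------------------------------------------------------------- #
# Independent brute-force oracle: enumerates the product lattice and solves
# the Moebius system by memoized recursion over explicitly computed down-sets.
# --------------------------------------------------------------------------- #

_COLLECTIONS = {"1": (0,), "2": (1,), "12": (0, 1)}
_NODES = (("1", "2"), ("1",), ("2",), ("12",))


def _leq(a, b):
    """a <= b iff every collection in b is a superset of some collection in a."""
    return all(
        any(set(_COLLECTIONS[ca]) <= set(_COLLECTIONS[cb]) for ca in a) for cb in b
    )


def _mi_det(cov, a_idx, b_idx):
    det = np.linalg.det
    a, b = list(a_idx), list(b_idx)
    return 0.5 * np.log(
        det(cov[np.ix_(a, a)]) * det(cov[np.ix_(b, b)]) / det(cov[np.ix_(a + b, a + b)])
    )


def brute_force_atoms(cov):
    """All 16 atoms by explicit recursion: atom(v) = cum(v) - sum(atoms below)."""
    pairs = list(itertools.product(_NODES, _NODES))

    def cum(node):
        alpha, beta = node
        return min(
            _mi_det(
                cov,
                _COLLECTIONS[ca],
                tuple(i + 2 for i in _COLLECTIONS[cb]),
            )
            for ca in alpha
            for cb in beta
        )

    memo = {}

    def atom(node):
        if node not in memo:
            below = [
                m
                for m in pairs
                if m != node and _leq(m[0], node[0]) and _leq(m[1], node[1])
            ]
            memo[node] = cum(node) - sum(atom(m) for m in below)
        return memo[node]

    chars = {("1", "2"): "r", ("1",): "x", ("2",): "y", ("12",): "s"}
    return {f"{chars[a]}t{chars[b]}": atom((a, b)) for a, b in pairs}


# --------------------------------------------------------------------------- #
# lagged covariance
# --------------------------------------------------------------------------- #


class TestLaggedCovariance:
    def test_ar1_autocovariance_matches_closed_form(self, rng):
        x = ar1_series(0.8, 50_000, rng)
        m = lagged_covariance(x, x.copy(), lag=1, standardize=True)
        # cov(x_{t-1}, x_t) = phi for a unit-variance AR(1)
        assert m.cov[0, 2] == pytest.approx(0.8, abs=0.02)

    def test_duplicated_channel_gives_rank_deficient_covariance(self, rng):
        x = rng.standard_normal(500)
        m = lagged_covariance(x, x.copy(), lag=1)
        np.testing.assert_allclose(m.cov[0], m.cov[1], atol=1e-6)
        np.testing.assert_allclose(m.cov[2], m.cov[3], atol=1e-6)
        assert m.condition_number > 1e12  # jitter path exercised

    def test_independent_white_noise_offdiagonals_vanish(self, rng):
        x = rng.standard_normal(100_000)
        y = rng.standard_normal(100_000)
        m = lagged_covariance(x, y, lag=1)
        off = m.cov[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.02

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            lagged_covariance(np.zeros(10), np.zeros(11), 1)

    def test_constant_series_rejected(self, rng):
        with pytest.raises(DegenerateInputError, match="constant"):
            lagged_covariance(np.ones(100), rng.standard_normal(100), 1)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="T > 4"):
            lagged_covariance(np.arange(8.0), np.arange(8.0), 2)


# --------------------------------------------------------------------------- #
# Gaussian MI
# --------------------------------------------------------------------------- #


class TestGaussianMI:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.0, 0.0), (0.9, -0.5 * np.log(1 - 0.81))],
        ids=["uncorrelated", "r=0.9"],
    )
    def test_bivariate_closed_form(self, r, expected):
        cov = np.eye(4)
        cov[0, 2] = cov[2, 0] = r
        m = LaggedGaussianModel(lag=1, cov=cov, n_samples=100)
        assert gaussian_mi(m, (0,), (2,)) == pytest.approx(expected, abs=1e-12)

    def test_joint_mi_symmetric_in_source_order(self, rng):
        cov = random_pd_cov(rng)
        m = LaggedGaussianModel(lag=1, cov=cov, n_samples=100)
        assert gaussian_mi(m, (0, 1), (2, 3)) == pytest.approx(
            gaussian_mi(m, (1, 0), (3, 2)), rel=1e-12
        )

    def test_overlapping_blocks_rejected(self, rng):
        m = LaggedGaussianModel(lag=1, cov=np.eye(4), n_samples=100)
        with pytest.raises(ValueError, match="disjoint"):
            gaussian_mi(m, (0, 1), (1, 2))


class TestDoubleRedundancy:
    def test_equals_minimum_of_four_channel_mis(self, rng):
        cov = random_pd_cov(rng)
        m = LaggedGaussianModel(lag=1, cov=cov, n_samples=100)
        mis = [gaussian_mi(m, (a,), (b,)) for a in (0, 1) for b in (2, 3)]
        assert double_redundancy_mmi(m) == pytest.approx(min(mis), rel=1e-12)

    def test_independent_channels_redundancy_vanishes(self, rng):
        x = rng.standard_normal(50_000)
        y = rng.standard_normal(50_000)
        m = lagged_covariance(x, y, 1)
        assert double_redundancy_mmi(m) < 1e-3

    def test_duplicated_ar1_equals_channel_self_information(self, rng):
        x = ar1_series(0.8, 100_000, rng)
        m = lagged_covariance(x, x.copy(), 1)
        expected = -0.5 * np.log(1 - 0.8**2)
        assert double_redundancy_mmi(m) == pytest.approx(expected, abs=0.02)


# --------------------------------------------------------------------------- #
# full decomposition
# --------------------------------------------------------------------------- #


class TestPhiIDDecompose:
    def test_conservation_on_random_models(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            cov = random_pd_cov(rng)
            m = LaggedGaussianModel(lag=1, cov=cov, n_samples=200)
            at = phiid_decompose(m)
            total = sum(at.atoms.values())
            assert total == pytest.approx(at.tdmi, rel=1e-8, abs=1e-12)

    def test_atoms_match_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        covs = [random_pd_cov(rng) for _ in range(3)]
        # block-diagonal: two independent lag-correlated channels
        block = np.eye(4)
        block[0, 2] = block[2, 0] = 0.7
        block[1, 3] = block[3, 1] = 0.4
        covs.append(block)
        for cov in covs:
            m = LaggedGaussianModel(lag=1, cov=cov, n_samples=200)
            got = phiid_decompose(m).atoms
            want = brute_force_atoms(cov)
            for name in ATOM_NAMES:
                assert got[name] == pytest.approx(want[name], rel=1e-8, abs=1e-10)

    def test_channel_swap_symmetry(self, rng):
        cov = random_pd_cov(rng)
        perm = [1, 0, 3, 2]  # swap x and y in past and present
        m1 = LaggedGaussianModel(lag=1, cov=cov, n_samples=200)
        m2 = LaggedGaussianModel(lag=1, cov=cov[np.ix_(perm, perm)], n_samples=200)
        a1, a2 = phiid_decompose(m1), phiid_decompose(m2)
        swap = str.maketrans("xy", "yx")
        for name in ATOM_NAMES:
            assert a1.atoms[name] == pytest.approx(
                a2.atoms[name.translate(swap)], rel=1e-9, abs=1e-12
            )
        assert a1.tdmi == pytest.approx(a2.tdmi, rel=1e-12)

    def test_duplicated_ar1_is_pure_persistent_redundancy(self, rng):
        x = ar1_series(0.8, 100_000, rng)
        at = phiid_decompose(lagged_covariance(x, x.copy(), 1))
        assert at.rtr == pytest.approx(at.tdmi, rel=1e-3)
        assert abs(at.sts) < 1e-6 * at.tdmi
        for u in ("xtx", "yty", "xty", "ytx"):
            assert abs(at.atoms[u]) < 1e-3 * at.tdmi

    def test_rtr_nonnegative(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            m = LaggedGaussianModel(lag=1, cov=random_pd_cov(rng), n_samples=200)
            assert phiid_decompose(m).rtr >= -1e-12

    def test_double_redundancy_lower_bounds_lattice(self, rng):
        m = LaggedGaussianModel(lag=1, cov=random_pd_cov(rng), n_samples=200)
        rtr_cum = double_redundancy_mmi(m)
        tdmi = gaussian_mi(m, (0, 1), (2, 3))
        assert rtr_cum <= tdmi + 1e-12


class TestPairwisePhiID:
    def test_matches_per_pair_decomposition(self, rng):
        data = rng.standard_normal((5, 400))
        # add shared structure so values are not all ~0
        data += 0.5 * np.cumsum(rng.standard_normal(400))[None, :] * 0.01
        mats = pairwise_phiid(data, lag=1)
        for i in range(5):
            for j in range(i + 1, 5):
                at = phiid_decompose(lagged_covariance(data[i], data[j], 1))
                assert mats["rtr"][i, j] == pytest.approx(at.rtr, rel=1e-8, abs=1e-10)
                assert mats["sts"][i, j] == pytest.approx(at.sts, rel=1e-8, abs=1e-10)
                assert mats["tdmi"][i, j] == pytest.approx(at.tdmi, rel=1e-8, abs=1e-10)

    def test_matrices_symmetric_with_zero_diagonal(self, rng):
        mats = pairwise_phiid(rng.standard_normal((6, 300)))
        for key in ("rtr", "sts", "tdmi"):
            np.testing.assert_allclose(mats[key], mats[key].T)
            assert np.all(np.diag(mats[key]) == 0)

    def test_constant_region_pairs_zeroed_with_warning(self, rng):
        data = rng.standard_normal((4, 300))
        data[2] = 5.0
        with pytest.warns(RuntimeWarning, match="constant"):
            mats = pairwise_phiid(data)
        assert np.all(mats["rtr"][2] == 0)
        assert np.all(mats["sts"][:, 2] == 0)
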