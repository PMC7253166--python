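import numpy as np
import pytest

from netcap import (
    ChainSpec,
    NetworkChannel,
    OptimizerOptions,
    build_chain,
    capacity,
    capacity_given_input,
    high_noise_rate,
    low_noise_rate,
    max_rate_over_T,
    normal_rate_bound,
    rate,
    scalar_capacity,
)
from netcap.capacity import LN2, _CapacityObjective
from conftest import random_stable


def simplex_grid_best(decay_rates, sigma2, T, step=0.01):
    """Brute-force power allocation over the probability simplex for a
    set of independent scalar channels (oracle for normal A, B=C=I)."""
    a = np.asarray(decay_rates, float)
    x = 2 * a * sigma2
    e = np.exp(-2 * a * T)
    best = 0.0
    k = int(round(1 / step))
    for i in range(k + 1):
        for j in range(k + 1 - i):
            p = np.array([i, j, k - i - j]) * step
            best = max(best, 0.5 * float(np.sum(np.log2((x + p) / (x + p * e)))))
    return best


class TestScalarCapacity:
    def test_single_node_value(self):
        # 1/2 log2(3/(2+e^-2)) at a = sigma2 = T = 1
        assert scalar_capacity(1.0, 1.0, 1.0) == pytest.approx(
            0.5 * np.log2(3.0 / (2.0 + np.exp(-2.0))), abs=1e-12
        )
        assert scalar_capacity(1.0, 1.0, 1.0) == pytest.approx(0.2452, abs=5e-4)

    def test_large_T_plateau(self):
        a, s2, p = 0.8, 0.5, 1.0
        plateau = 0.5 * np.log2(1 + p / (2 * a * s2))
        assert scalar_capacity(a, s2, 200.0, p) == pytest.approx(plateau, rel=1e-9)

    def test_vanishes_for_extreme_decay_rates(self):
        assert scalar_capacity(1e-9, 1.0, 1.0) == pytest.approx(0.0, abs=1e-6)
        assert scalar_capacity(1e9, 1.0, 1.0) == pytest.approx(0.0, abs=1e-6)

    def test_domain_errors(self):
        for bad in [(-1, 1, 1), (1, 0, 1), (1, 1, 0)]:
            with pytest.raises(ValueError):
                scalar_capacity(*bad)


class TestCapacityGivenInput:
    @pytest.mark.parametrize("a", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("sigma2", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("T", [0.1, 1.0, 5.0])
    def test_scalar_master_oracle(self, a, sigma2, T):
        """The full Gramian + determinant pipeline on a 1x1 channel must
        reproduce the closed form to near machine precision."""
        ch = NetworkChannel(A=[[-a]], T=T, sigma2=sigma2)
        assert capacity_given_input(ch, [[1.0]]) == pytest.approx(
            scalar_capacity(a, sigma2, T), abs=1e-9
        )

    def test_zero_input_gives_zero_bits(self):
        ch = NetworkChannel(A=random_stable(3, 0), T=1.0, sigma2=1.0)
        assert capacity_given_input(ch, np.zeros((3, 3))) == 0.0

    def test_diagonal_channel_decomposes(self):
        # independent nodes with diagonal input covariance = sum of
        # scalar capacities per mode
        a = np.array([0.5, 2.0])
        p = np.array([0.3, 0.7])
        ch = NetworkChannel(A=np.diag(-a), T=1.2, sigma2=0.8)
        expected = sum(scalar_capacity(ai, 0.8, 1.2, pi) for ai, pi in zip(a, p))
        assert capacity_given_input(ch, np.diag(p)) == pytest.approx(expected, abs=1e-9)

    def test_rejects_indefinite_sigma(self):
        ch = NetworkChannel(A=random_stable(2, 1), T=1.0)
        with pytest.raises(ValueError):
            capacity_given_input(ch, np.array([[1.0, 0.0], [0.0, -0.5]]))

    def test_analytic_gradient_matches_finite_differences(self, rng):
        obj = _CapacityObjective(
            NetworkChannel(A=build_chain(ChainSpec(4, 3.0)), T=0.7, sigma2=2.0)
        )
        F = rng.standard_normal((4, 4))
        S = F @ F.T
        S /= np.trace(S)
        G = obj.gradient(S)
        eps = 1e-6
        for i in range(4):
            for j in range(i, 4):
                Eij = np.zeros((4, 4))
                Eij[i, j] = Eij[j, i] = 1.0
                fd = (obj.value(S + eps * Eij) - obj.value(S - eps * Eij)) / (2 * eps)
                fd /= 1.0 if i == j else 2.0
                assert G[i, j] == pytest.approx(fd, abs=1e-7)


class TestCapacity:
    def test_single_node(self):
        res = capacity(NetworkChannel(A=[[-1.0]], T=1.0, sigma2=1.0))
        assert res.capacity_bits == pytest.approx(scalar_capacity(1, 1, 1), abs=1e-10)
        assert res.rate_bits_per_time == pytest.approx(res.capacity_bits)
        assert res.converged

    def test_identical_nodes_share_power_equally(self):
        n = 4
        res = capacity(NetworkChannel(A=-np.eye(n), T=1.0, sigma2=1.0))
        assert np.linalg.norm(res.sigma_opt - np.eye(n) / n) < 1e-3
        assert res.capacity_bits == pytest.approx(
            n * scalar_capacity(1.0, 1.0, 1.0, 1.0 / n), abs=1e-6
        )
        assert res.input_dimensionality == pytest.approx(n, abs=1e-6)

    def test_normal_shortcut_matches_simplex_oracle(self):
        A = np.diag([-0.5, -1.0, -2.0])
        res = capacity(NetworkChannel(A=A, T=1.0, sigma2=1.0))
        oracle = simplex_grid_best([0.5, 1.0, 2.0], 1.0, 1.0)
        assert res.capacity_bits >= oracle - 1e-9  # grid is a lower bound
        assert res.capacity_bits == pytest.approx(oracle, abs=1e-4)

    def test_general_optimizer_matches_simplex_oracle(self):
        """Dual-route check: the factor-gradient search (no normal-A
        shortcut) agrees with the brute-force allocation oracle."""
        from netcap.optimize import optimize_input_covariance

        ch = NetworkChannel(A=np.diag([-0.5, -1.0, -2.0]), T=1.0, sigma2=1.0)
        obj = _CapacityObjective(ch)
        _, val, _ = optimize_input_covariance(
            obj.value, 3, OptimizerOptions(n_restarts=5, seed=0),
            gradient=obj.gradient,
        )
        assert val == pytest.approx(simplex_grid_best([0.5, 1.0, 2.0], 1.0, 1.0), abs=1e-4)

    def test_capacity_increases_with_snr(self):
        A = build_chain(ChainSpec(5, 3.0))
        opts = OptimizerOptions(n_restarts=3, seed=0)
        caps = [capacity(NetworkChannel(A=A, T=1.0, sigma2=s2), opts).capacity_bits
                for s2 in [4.0, 1.0, 0.25, 0.05]]
        assert np.all(np.diff(caps) > 0)

    def test_adding_output_nodes_never_decreases_capacity(self):
        A = random_stable(4, 8)
        opts = OptimizerOptions(n_restarts=4, seed=0)
        C2 = np.eye(4)[:2]
        C3 = np.eye(4)[:3]
        c2 = capacity(NetworkChannel(A=A, T=1.0, sigma2=1.0, C=C2), opts).capacity_bits
        c3 = capacity(NetworkChannel(A=A, T=1.0, sigma2=1.0, C=C3), opts).capacity_bits
        c4 = capacity(NetworkChannel(A=A, T=1.0, sigma2=1.0), opts).capacity_bits
        assert c2 <= c3 + 1e-6 <= c4 + 2e-6

    def test_rate_is_capacity_over_T(self):
        ch = NetworkChannel(A=random_stable(3, 4), T=2.5, sigma2=1.0)
        res = rate(ch, OptimizerOptions(n_restarts=2, seed=0))
        assert res.rate_bits_per_time == pytest.approx(res.capacity_bits / 2.5)


class TestChannelValidation:
    def test_rejects_unstable_A(self):
        with pytest.raises(ValueError, match="stable"):
            NetworkChannel(A=[[0.1]], T=1.0)

    def test_rejects_zero_noise(self):
        with pytest.raises(ValueError, match="sigma2"):
            NetworkChannel(A=[[-1.0]], T=1.0, sigma2=0.0)

    def test_rejects_tiny_window(self):
        with pytest.raises(ValueError, match="T must be"):
            NetworkChannel(A=[[-1.0]], T=1e-5)

    def test_warns_on_rank_deficient_selectors(self):
        with pytest.warns(UserWarning, match="rank deficient"):
            NetworkChannel(A=random_stable(3, 2), T=1.0,
                           B=np.array([[1.0, 1.0], [1.0, 1.0], [0.0, 0.0]]))


class TestRateOverT:
    def test_single_node_boundary_maximum(self):
        T_grid = np.geomspace(0.01, 5.0, 12)
        mr = max_rate_over_T(np.array([[-1.0]]), T_grid, sigma2=1.0)
        assert mr.boundary
        assert mr.T_opt == T_grid[0]
        # R_T -> a/((1+2a sigma2) ln 2) as T -> 0
        assert mr.R_max == pytest.approx(1.0 / (3.0 * LN2), rel=0.01)
        assert np.all(np.diff(mr.rates) < 0)

    def test_nonnormal_chain_has_interior_maximum(self):
        A = build_chain(ChainSpec(8, 7.0))
        T_grid = np.geomspace(0.2, 8.0, 8)
        mr = max_rate_over_T(A, T_grid, sigma2=1.0,
                             opts=OptimizerOptions(n_restarts=3, seed=0))
        assert not mr.boundary
        assert T_grid[0] < mr.T_opt < T_grid[-1]

    def test_rmax_nonincreasing_in_noise(self):
        A = build_chain(ChainSpec(5, 5.0))
        T_grid = np.geomspace(0.1, 5.0, 6)
        opts = OptimizerOptions(n_restarts=2, seed=0)
        r = [max_rate_over_T(A, T_grid, sigma2=s2, opts=opts, refine=False).R_max
             for s2 in [0.1, 1.0, 10.0]]
        assert r[0] >= r[1] >= r[2]

    def test_empty_or_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            max_rate_over_T(np.array([[-1.0]]), [])
        with pytest.raises(ValueError):
            max_rate_over_T(np.array([[-1.0]]), [1.0, 0.5])


class TestBoundsAndAsymptotics:
    def test_normal_rate_bound_value(self):
        assert normal_rate_bound(-20.0, 1.0) == pytest.approx((1 / LN2) * 20 / 41)
        assert normal_rate_bound(-20.0, 1.0) == pytest.approx(0.7037, abs=1e-4)

    def test_normal_rate_bound_low_snr_limit(self):
        s2 = 1e6
        for trA in [-1.0, -20.0, -300.0]:
            assert normal_rate_bound(trA, s2) == pytest.approx(
                1.0 / (2 * LN2 * s2), rel=1e-3
            )

    def test_normal_rate_bound_domain(self):
        with pytest.raises(ValueError):
            normal_rate_bound(1.0, 1.0)

    def test_low_noise_rate_chain(self):
        A = build_chain(ChainSpec(8, 7.0))
        assert low_noise_rate(A) == pytest.approx(20.0 / LN2)

    def test_high_noise_rate_scalar_reduction(self):
        a, T, s2 = 0.7, 1.3, 50.0
        ch = NetworkChannel(A=[[-a]], T=T, sigma2=s2)
        expected = (1 - np.exp(-2 * a * T)) / (4 * a * LN2 * T * s2)
        assert high_noise_rate(ch) == pytest.approx(expected, rel=1e-10)

    def test_beta_does_not_affect_high_noise_chain_rmax(self):
        # at poor SNR the peak rate of the normal chain depends only on
        # the spectrum's trace, not the coupling strength
        opts = OptimizerOptions(n_restarts=2, seed=0)
        T_grid = np.geomspace(1e-3, 0.1, 5)
        rates = []
        for beta in [0.5, 1.0, 2.0]:
            A = build_chain(ChainSpec(6, 1.0, beta=beta, gamma=-5.0))
            rates.append(max_rate_over_T(A, T_grid, sigma2=1e4, opts=opts,
                                         refine=False).R_max)
        assert max(rates) / min(rates) < 1.02
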