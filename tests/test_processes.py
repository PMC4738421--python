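import numpy as np
import pytest
from hypothesis import given

from mitoq import (
    QualityDistribution,
    apply_external_damage,
    dP_ec,
    dP_ff_metabolic,
    dP_ff_protein,
    dP_mb,
    dP_repair,
    ec_kernel,
    hill_rate,
    reference_parameters,
    repair_kernel,
    rho_of_t,
)
import mitoq.processes as mp

from . import oracles
from .conftest import distributions, random_distribution

PARAMS = reference_parameters()

DETERMINISTIC_OPS = {
    "ff_metabolic": dP_ff_metabolic,
    "ff_protein": dP_ff_protein,
    "mb": dP_mb,
    "repair": dP_repair,
    "ec": dP_ec,
}


def qbar(p):
    return float(np.arange(len(p)) @ p)


class TestMetabolicFF:
    @pytest.mark.parametrize("q_star", [0, 3, 10])
    def test_single_occupied_state_is_inert(self, q_star):
        """A single occupied state has no partner of different quality."""
        P = QualityDistribution.delta(10, q_star)
        assert np.all(dP_ff_metabolic(P, 0.0, PARAMS) == 0)

    def test_two_state_example(self):
        """P(2)=P(4)=0.5, Q=4: both ordered (2,4) pairs mix into q=3."""
        P = QualityDistribution(np.array([0, 0, 0.5, 0, 0.5]))
        dP = dP_ff_metabolic(P, 0.0, PARAMS)
        w = 0.05 * 0.25 * hill_rate(2, 2, 3)  # per ordered pair
        np.testing.assert_allclose(dP, [0, 0, -2 * w, 4 * w, -2 * w], atol=1e-15)
        assert abs(np.arange(5) @ dP) < 1e-16

    @given(P=distributions(min_Q=4))
    def test_conserves_mass_and_first_moment(self, P):
        dP = dP_ff_metabolic(P, 100.0, PARAMS)
        assert abs(dP.sum()) < 1e-14
        assert abs(np.arange(P.Q + 1) @ dP) < 1e-14


class TestProteinFF:
    def test_inactive_only_is_inert(self):
        P = QualityDistribution.delta(10, 0)
        assert np.all(dP_ff_protein(P, 0.0, PARAMS) == 0)

    def test_top_state_cannot_fission(self):
        """At q=Q the fission Hill rate hill(Q-Q)=0, and fusion needs a pair."""
        P = QualityDistribution.delta(10, 10)
        assert np.all(dP_ff_protein(P, 0.0, PARAMS) == 0)

    def test_two_state_example(self):
        """P(1)=P(5)=0.5: fusion raises q=1 to q=5, fission feeds q=0."""
        v = np.zeros(11)
        v[1] = v[5] = 0.5
        P = QualityDistribution(v)
        t = 0.0
        dP = dP_ff_protein(P, t, PARAMS)
        rho_fu = rho_of_t(PARAMS.law_ffp_fusion, t)
        rho_fi = rho_of_t(PARAMS.law_ffp_fission, t)
        w = 2 * rho_fu * 0.25 * hill_rate(4, 2, 3)
        v1 = 2 * rho_fi * 0.25 * hill_rate(9, 2, 3)
        v5 = 2 * rho_fi * 0.25 * hill_rate(5, 2, 3)
        expected = np.zeros(11)
        expected[5] += w
        expected[1] -= w
        expected[0] += v1 + v5
        expected[1] -= v1
        expected[5] -= v5
        np.testing.assert_allclose(dP, expected, atol=1e-15)

    @given(P=distributions(min_Q=4))
    def test_conserves_mass(self, P):
        assert abs(dP_ff_protein(P, 500.0, PARAMS).sum()) < 1e-14


class TestMitophagyBiogenesis:
    def test_no_inactive_mass_is_inert(self):
        P = QualityDistribution.delta(10, 5)
        assert np.all(dP_mb(P, 0.0, PARAMS) == 0)

    def test_direct_flux(self):
        """Half the mass inactive, rho_mb=0.01: flux 0.005 from q=0 to q=Q."""
        v = np.zeros(11)
        v[0] = v[4] = 0.5
        dP = dP_mb(QualityDistribution(v), 0.0, PARAMS)
        assert dP[0] == pytest.approx(-0.005)
        assert dP[10] == pytest.approx(0.005)
        assert np.all(dP[1:10] == 0)

    @given(P=distributions(min_Q=4))
    def test_conserves_mass(self, P):
        assert abs(dP_mb(P, 1000.0, PARAMS).sum()) < 1e-15


class TestBinomialKernels:
    def test_repair_extremes(self):
        np.testing.assert_allclose(repair_kernel(0.0, 10), np.eye(11), atol=0)
        K = repair_kernel(1.0, 10)
        assert np.all(K[:, :-1] == 0) and np.all(K[:, -1] == 1)

    def test_ec_extremes(self):
        np.testing.assert_allclose(ec_kernel(0.0, 10), np.eye(11), atol=0)
        K = ec_kernel(1.0, 10)
        assert np.all(K[:, 1:] == 0) and np.all(K[:, 0] == 1)

    @pytest.mark.parametrize("rho", [0.0, 1e-6, 0.01, 0.3, 0.9999, 1.0])
    @pytest.mark.parametrize("Q", [4, 10, 14])
    def test_row_stochastic(self, rho, Q):
        for K in (repair_kernel(rho, Q), ec_kernel(rho, Q)):
            assert np.all(K >= 0)
            np.testing.assert_allclose(K.sum(axis=1), 1.0, atol=1e-12)

    def test_ec_mean_loss_is_q_times_rho(self):
        """Binomial mean: state q loses q*rho quality units in expectation."""
        rho, Q = 0.2, 10
        K = ec_kernel(rho, Q)
        means = K @ np.arange(Q + 1)
        np.testing.assert_allclose(means, np.arange(Q + 1) * (1 - rho), atol=1e-12)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            repair_kernel(1.2, 10)
        with pytest.raises(ValueError):
            ec_kernel(-0.1, 10)


class TestRepairAndEcFlux:
    def test_zero_rate_is_inert(self):
        P = QualityDistribution.uniform(10)
        params = reference_parameters(rho0_rep=0.0, rho0_ec=0.0)
        assert np.all(dP_repair(P, 0.0, params) == 0)
        assert np.all(dP_ec(P, 0.0, params) == 0)

    def test_certain_repair_from_inactive(self):
        """With per-unit repair probability 1, the inactive state jumps to Q."""
        params = reference_parameters(rho0_rep=1.0, tau_rep=5e8)
        dP = dP_repair(QualityDistribution.delta(10, 0), 0.0, params)
        assert dP[0] == pytest.approx(-1.0)
        assert dP[10] == pytest.approx(1.0)

    def test_certain_loss_from_top(self):
        params = reference_parameters(rho0_ec=1.0, tau_ec=5e8)
        dP = dP_ec(QualityDistribution.delta(10, 10), 0.0, params)
        assert dP[10] == pytest.approx(-1.0)
        assert dP[0] == pytest.approx(1.0)

    def test_monotone_moment_shift(self, rng):
        """Repair never lowers, energy consumption never raises, qbar."""
        for _ in range(25):
            P = random_distribution(rng, 10)
            up = dP_repair(P, 0.0, PARAMS)
            down = dP_ec(P, 0.0, PARAMS)
            assert np.arange(11) @ up >= -1e-14
            assert np.arange(11) @ down <= 1e-14
            assert abs(up.sum()) < 1e-14 and abs(down.sum()) < 1e-14


class TestOracleEquivalence:
    """Vectorized operators vs literal nested-loop transcriptions, Q <= 6."""

    @pytest.mark.parametrize("Q", [2, 4, 6])
    @pytest.mark.parametrize("t", [0.0, 12_345.0])
    def test_all_deterministic_operators(self, Q, t, rng):
        for _ in range(10):
            P = random_distribution(rng, Q)
            p = P.probs
            np.testing.assert_allclose(
                dP_ff_metabolic(P, t, PARAMS),
                oracles.naive_ffm(p, rho_of_t(PARAMS.law_ffm, t), 2, 3),
                atol=1e-12,
            )
            np.testing.assert_allclose(
                dP_ff_protein(P, t, PARAMS),
                oracles.naive_ffp(
                    p,
                    rho_of_t(PARAMS.law_ffp_fusion, t),
                    rho_of_t(PARAMS.law_ffp_fission, t),
                    2,
                    3,
                ),
                atol=1e-12,
            )
            np.testing.assert_allclose(
                dP_mb(P, t, PARAMS), oracles.naive_mb(p, rho_of_t(PARAMS.law_mb, t)),
                atol=1e-12,
            )
            np.testing.assert_allclose(
                dP_repair(P, t, PARAMS),
                oracles.naive_repair(p, rho_of_t(PARAMS.law_rep, t)),
                atol=1e-12,
            )
            np.testing.assert_allclose(
                dP_ec(P, t, PARAMS), oracles.naive_ec(p, rho_of_t(PARAMS.law_ec, t)),
                atol=1e-12,
            )


class _ForcedRng:
    """Deterministic stand-in for a Generator: always fires, fixed pair."""

    def __init__(self, pair_index):
        self.pair_index = pair_index

    def random(self):
        return 0.0

    def integers(self, n):
        return self.pair_index


class TestExternalDamage:
    def test_zero_fraction_is_identity(self):
        params = reference_parameters(f_rd=0.0)
        P = QualityDistribution.uniform(10)
        out = apply_external_damage(P, 0.0, params, np.random.default_rng(0))
        np.testing.assert_array_equal(out.probs, P.probs)

    def test_forced_top_to_bottom_transfer(self):
        """A forced (q'=Q, q=0) event moves the fraction f_rd of P(Q)."""
        params = reference_parameters(f_rd=0.3)
        P = QualityDistribution.delta(10, 10)
        idx = mp._ed_pairs(10).index((10, 0))
        out = apply_external_damage(P, 0.0, params, _ForcedRng(idx))
        assert out.probs[10] == pytest.approx(0.7)
        assert out.probs[0] == pytest.approx(0.3)

    def test_mass_conserved_and_moment_never_increases(self, rng):
        params = reference_parameters()
        for _ in range(50):
            P = random_distribution(rng, 10)
            out = apply_external_damage(P, 90_000.0, params, rng)
            assert abs(out.probs.sum() - P.probs.sum()) < 1e-15
            assert qbar(out.probs) <= qbar(P.probs) + 1e-14
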