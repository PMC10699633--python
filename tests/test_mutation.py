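"""Yule-Furry mutation law, tau-leaping and the combined acceptance
probability, checked against event-driven birth-process simulation,
inverse-CDF statistics and direct product-distribution Monte Carlo."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mammosim.core import (CellPopulation, CellRecord, Fields, N_GENES,
                           SimulationConfig, make_initial_state)
from mammosim.mutation import (MutationState, acceptance_probability,
                               hopping_probability, mutation_sweep,
                               sample_tau, tau_leap_update, yule_pmf)


class TestHopping:
    def test_zero_glucose(self):
        assert hopping_probability(0.0, 0.3) == 1.0

    def test_characteristic_scale(self):
        assert hopping_probability(0.3, 0.3) == pytest.approx(math.exp(-1))

    def test_table_value(self):
        # theta_div = 0.3 and C1 = 0.3 force exp(-1)
        assert hopping_probability(0.3, 0.3) == pytest.approx(0.367879,
                                                              abs=1e-6)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            hopping_probability(-1.0, 0.3)


class TestYulePmf:
    def test_degenerate(self):
        assert yule_pmf(1, 1.0) == 1.0
        assert yule_pmf(5, 1.0) == 0.0

    def test_geometric_values(self):
        assert yule_pmf(np.array([1, 2, 3]), 0.5) == pytest.approx(
            [0.5, 0.25, 0.125])

    def test_rejects_zero_count(self):
        with pytest.raises(ValueError):
            yule_pmf(0, 0.5)

    def test_sums_to_one_with_mean(self):
        x = np.arange(1, 2000)
        p = 0.3
        pmf = yule_pmf(x, p)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-6)
        assert (x * pmf).sum() == pytest.approx(1 / p, rel=1e-4)

    def test_matches_event_driven_birth_process(self, rng):
        """A continuous-time pure-birth process (rate gamma per lineage)
        observed at time t has geometric counts with p = exp(-gamma t)."""
        gamma, t, n = 0.7, 1.3, 100_000
        counts = np.empty(n, dtype=int)
        for i in range(n):
            x, now = 1, 0.0
            while True:
                now += rng.exponential(1.0 / (gamma * x))
                if now > t:
                    break
                x += 1
            counts[i] = x
        p = math.exp(-gamma * t)
        kmax = 40
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        expected = n * yule_pmf(np.arange(1, kmax), p)
        tail = n * (1 - p) ** (kmax - 1)
        obs = np.concatenate([observed[1:kmax], [observed[kmax]]])
        exp = np.concatenate([expected, [tail]])
        chi2 = ((obs - exp) ** 2 / exp).sum()
        dof = len(exp) - 1
        assert chi2 < stats.chi2.ppf(0.999, dof)


class TestAcceptance:
    def test_reduces_to_p_without_estrogen_failure(self):
        assert acceptance_probability(0.37, 0.9, 0.0) == pytest.approx(0.37)

    def test_full_union(self):
        assert acceptance_probability(0.0, 1.0, 1.0) == 1.0

    def test_worked_value(self):
        assert acceptance_probability(0.4, 0.5, 0.5) == pytest.approx(0.55)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            acceptance_probability(1.2, 0.5, 0.5)

    @given(p=st.floats(0, 1), b=st.floats(0, 1), pb=st.floats(0, 1),
           dp=st.floats(0, 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_and_monotonicity(self, p, b, pb, dp):
        val = acceptance_probability(p, b, pb)
        assert 0.0 <= val <= 1.0
        b2 = min(1.0, b + dp)
        assert acceptance_probability(p, b2, pb) >= val - 1e-12


class TestTau:
    def test_forced_value(self):
        assert sample_tau(10.0, math.exp(-10)) == pytest.approx(1.0)

    def test_limit_r_to_one(self):
        assert sample_tau(10.0, 1 - 1e-12) < 1e-11

    def test_rejects_r_zero(self):
        with pytest.raises(ValueError):
            sample_tau(10.0, 0.0)

    def test_exponential_distribution(self, rng):
        a0, n = 10.0, 100_000
        taus = sample_tau(a0, rng.uniform(size=n))
        d, pval = stats.kstest(taus, "expon", args=(0, 1 / a0))
        assert pval > 1e-3


class TestTauLeap:
    def test_zero_poisson_mean_changes_nothing(self, rng):
        state = MutationState(x=np.zeros(N_GENES, dtype=int), p_hop=0.5)
        out = tau_leap_update(state, 0.0, rng)
        assert out.x.sum() == 0

    def test_per_gene_increment_capped_at_one(self, rng):
        state = MutationState(x=np.zeros(N_GENES, dtype=int), p_hop=1e-6)
        for _ in range(200):
            out = tau_leap_update(state, 50.0, rng)
            assert ((out.x - state.x) <= 1).all()
            assert ((out.x - state.x) >= 0).all()
            state = out

    def test_increment_distribution_matches_product_oracle(self, rng):
        """P(increment) = P(k z >= 1), k ~ Poisson(m tau), z ~ Geom(p)."""
        m, p, n = 5.0, 0.4, 100_000
        hits = 0
        taus = np.log(1 / rng.uniform(size=n)) / 10.0
        ks = rng.poisson(m * taus)
        zs = rng.geometric(p, size=n)
        oracle = float(((ks * zs) >= 1).mean())
        state = MutationState(x=np.zeros(N_GENES, dtype=int), p_hop=p)
        rng2 = np.random.default_rng(777)
        for _ in range(n // 10):
            out = tau_leap_update(state, m, rng2)
            hits += int(out.x.sum() > state.x.sum())
        freq = hits / (n // 10)
        sigma = math.sqrt(oracle * (1 - oracle) / (n // 10))
        assert abs(freq - oracle) < 4 * sigma


def _population_of(n, config, genotype_seed=0):
    grid, cells, fields = make_initial_state(config)
    cells = CellPopulation()
    rng = np.random.default_rng(genotype_seed)
    for i in range(n):
        pos = (int(rng.integers(config.L)), int(rng.integers(config.L)))
        rec = CellRecord(pos=pos,
                         genotype=np.zeros(N_GENES, dtype=np.int64),
                         eta=np.full(N_GENES, 0.5),
                         eta0=np.full(N_GENES, 0.5),
                         grn_state=np.zeros(N_GENES),
                         phase=(1.2, 1.0))
        cells.add(rec)
    return cells, fields


class TestSweep:
    def test_certain_acceptance_conventional(self, small_config, rng):
        small_config.mutation_rule = "conventional"
        small_config.P_B = 1.0
        cells, fields = _population_of(50, small_config)
        fields.C1[...] = 0.0              # p = 1 -> Prm = 1
        fired = mutation_sweep(cells, fields, np.ones(50), small_config, rng)
        assert len(fired) == 50

    def test_certain_acceptance_as_printed_never_fires(self, small_config,
                                                       rng):
        small_config.mutation_rule = "as_printed"
        cells, fields = _population_of(50, small_config)
        fields.C1[...] = 0.0
        fired = mutation_sweep(cells, fields, np.ones(50), small_config, rng)
        assert len(fired) == 0

    def test_firing_frequency_tracks_acceptance_probability(self,
                                                            small_config):
        small_config.mutation_rule = "conventional"
        small_config.P_B = 0.0
        n, reps = 200, 50
        cells, fields = _population_of(n, small_config)
        fields.C1[...] = 0.3              # p = exp(-1)
        prm = math.exp(-1)
        rng = np.random.default_rng(99)
        fired = sum(len(mutation_sweep(cells, fields, np.zeros(n),
                                       small_config, rng))
                    for _ in range(reps))
        total = n * reps
        sigma = math.sqrt(total * prm * (1 - prm))
        assert abs(fired - total * prm) < 4 * sigma

    def test_genotype_monotone_nondecreasing(self, small_config):
        cells, fields = _population_of(30, small_config)
        fields.C1[...] = 0.05
        rng = np.random.default_rng(5)
        before = np.array([c.genotype.copy() for c in cells.cells])
        for _ in range(20):
            mutation_sweep(cells, fields, np.full(30, 0.5), small_config,
                           rng)
            now = np.array([c.genotype for c in cells.cells])
            assert (now >= before).all()
            before = now.copy()
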