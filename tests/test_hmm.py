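import itertools
import math

import numpy as np
import pytest

from kinmix import (
    AncestralConfiguration,
    FounderModel,
    PhasedGenome,
    SiteTable,
    ancestry_step_prob,
    emission_prob,
    forward_step_dc,
    init_distribution,
    loglikelihood,
    n_states,
    phase_step_prob,
    recomb_step_prob,
    transition_prob,
)
from kinmix.ac import decode_ac, founder_of, n_bits, n_founders
from kinmix.hmm import OpCounter, chain_arrays, emission_vector, forward_scan

from conftest import random_genome, random_model, random_sites


# ----------------------------------------------------------------------
# independent oracles (first principles, no shared code with the package
# beyond the bit layout definition)
# ----------------------------------------------------------------------
def oracle_bit_step(prev, cur, sw):
    sw = min(sw, 0.5)
    return sw if prev != cur else 1.0 - sw


def oracle_transition(i_from, i_to, d, rec, model):
    """Transition probability computed bit by bit from decoded states."""
    K = model.K
    Pf, Cf, Rf = decode_ac(i_from, K)
    Pt, Ct, Rt = decode_ac(i_to, K)
    p = oracle_bit_step(Pf, Pt, d * model.pp)
    for j in range(n_founders(K)):
        rate = model.rateAB[j] if Cf[j] == 0 else model.rateBA[j]
        p *= oracle_bit_step(Cf[j], Ct[j], d * rate)
    for k in range(n_founders(K) - 2):
        p *= oracle_bit_step(Rf[k], Rt[k], rec)
    return p


def oracle_dense_T(d, rec, model):
    N = n_states(model.K)
    T = np.empty((N, N))
    for i in range(N):
        for j in range(N):
            T[j, i] = oracle_transition(i, j, d, rec, model)
    return T


def oracle_emission(idx, a1, a2, fA, fB, K):
    P, C, R = decode_ac(idx, K)
    p = 1.0
    for hap, allele in ((1, a1), (2, a2)):
        pop = C[founder_of(hap, P, R, K) - 1]
        f = fB if pop == 1 else fA
        p *= f if allele == 1 else 1.0 - f
    return p


def oracle_init(idx, model):
    P, C, R = decode_ac(idx, model.K)
    m0 = model.rateBA / (model.rateAB + model.rateBA)
    p = 0.5
    for j, c in enumerate(C):
        p *= m0[j] if c == 0 else 1.0 - m0[j]
    return p * 0.5 ** len(R)


def oracle_path_enum_loglik(genome, sites, model):
    """Explicit sum over every hidden-state path (linked single chain)."""
    N = n_states(model.K)
    gap, rec = chain_arrays(sites)
    n = sites.n
    total = 0.0
    for path in itertools.product(range(N), repeat=n):
        p = oracle_init(path[0], model) * oracle_emission(
            path[0], genome.h1[0], genome.h2[0], sites.freqA[0], sites.freqB[0],
            model.K)
        for i in range(1, n):
            p *= oracle_transition(path[i - 1], path[i], gap[i], rec[i], model)
            p *= oracle_emission(path[i], genome.h1[i], genome.h2[i],
                                 sites.freqA[i], sites.freqB[i], model.K)
        total += p
    return math.log(total)


def oracle_dense_forward_loglik(genome, sites, model):
    """Dense-matrix forward pass (sum over paths by distributivity)."""
    N = n_states(model.K)
    gap, rec = chain_arrays(sites)
    v = np.array([oracle_init(s, model) * oracle_emission(
        s, genome.h1[0], genome.h2[0], sites.freqA[0], sites.freqB[0], model.K)
        for s in range(N)])
    for i in range(1, sites.n):
        T = oracle_dense_T(gap[i], rec[i], model)
        e = np.array([oracle_emission(s, genome.h1[i], genome.h2[i],
                                      sites.freqA[i], sites.freqB[i], model.K)
                      for s in range(N)])
        v = (T @ v) * e
    return math.log(v.sum())


# ----------------------------------------------------------------------
# step probabilities
# ----------------------------------------------------------------------
class TestStepProbs:
    def test_zero_distance(self):
        assert ancestry_step_prob(0, 0, 0, 1e-7, 1e-7) == 1.0
        assert ancestry_step_prob(0, 1, 0, 1e-7, 1e-7) == 0.0

    def test_linear_regime(self):
        assert ancestry_step_prob(0, 1, 1000, 1e-7, 5e-7) == pytest.approx(1e-4)
        assert ancestry_step_prob(0, 0, 1000, 1e-7, 5e-7) == pytest.approx(0.9999)

    def test_clamp(self):
        # d * rate = 10 clamps to the 0.5 cap
        assert ancestry_step_prob(0, 1, 1e7, 1e-6, 1e-6) == 0.5
        assert ancestry_step_prob(0, 0, 1e7, 1e-6, 1e-6) == 0.5

    def test_negative_distance(self):
        with pytest.raises(ValueError):
            ancestry_step_prob(0, 1, -1, 1e-7, 1e-7)

    def test_pair_sums_to_one(self, rng):
        for _ in range(20):
            d = float(rng.uniform(0, 1e7))
            r1, r2 = rng.uniform(1e-9, 1e-5, 2)
            for prev in (0, 1):
                s = ancestry_step_prob(prev, 0, d, r1, r2) + \
                    ancestry_step_prob(prev, 1, d, r1, r2)
                assert s == pytest.approx(1.0)

    def test_phase(self):
        assert phase_step_prob(0, 1, 0, 2e-5) == 0.0
        assert phase_step_prob(0, 1, 500, 2e-5) == pytest.approx(0.01)
        assert phase_step_prob(0, 0, 500, 2e-5) == pytest.approx(0.99)
        assert phase_step_prob(0, 0, 12345, 0.0) == 1.0

    def test_recomb(self):
        assert recomb_step_prob(0, 1, 0.0) == 0.0
        assert recomb_step_prob(0, 0, 0.0) == 1.0
        assert recomb_step_prob(0, 1, 0.01) == 0.01
        for r in (0.0, 0.1, 0.5):
            assert recomb_step_prob(0, 0, r) + recomb_step_prob(0, 1, r) == 1.0
        with pytest.raises(ValueError):
            recomb_step_prob(0, 1, 0.7)


class TestTransitionProb:
    def test_self_transition_value(self):
        model = FounderModel(1, [1e-7, 1e-7], [1e-7, 1e-7], pp=1e-5)
        ac = AncestralConfiguration(K=1, P=0, C=(0, 1), R=())
        p = transition_prob(ac, ac, d=100, rec_prob=0.0, model=model)
        assert p == pytest.approx((1 - 1e-3) * (1 - 1e-5) ** 2, rel=1e-12)
        assert p == pytest.approx(0.998980, abs=5e-7)

    @pytest.mark.parametrize("K", [1, 2])
    def test_rows_sum_to_one(self, K, rng):
        model = random_model(rng, K, pp=1e-5)
        i_from = int(rng.integers(0, n_states(K)))
        ac_from = AncestralConfiguration.from_index(i_from, K)
        tot = sum(
            transition_prob(ac_from, AncestralConfiguration.from_index(j, K),
                            d=777.0, rec_prob=0.02, model=model)
            for j in range(n_states(K)))
        assert tot == pytest.approx(1.0, abs=1e-12)

    def test_identity_at_zero(self, rng):
        model = random_model(rng, 2, pp=1e-5)
        a = AncestralConfiguration.from_index(37, 2)
        b = AncestralConfiguration.from_index(38, 2)
        assert transition_prob(a, a, 0.0, 0.0, model) == 1.0
        assert transition_prob(a, b, 0.0, 0.0, model) == 0.0

    def test_mismatched_K(self, rng):
        model = random_model(rng, 1)
        a = AncestralConfiguration.from_index(0, 1)
        b = AncestralConfiguration.from_index(0, 2)
        with pytest.raises(ValueError):
            transition_prob(a, b, 1.0, 0.0, model)

    def test_matches_oracle(self, rng):
        model = random_model(rng, 2, pp=3e-6)
        for _ in range(30):
            i, j = rng.integers(0, n_states(2), 2)
            a = AncestralConfiguration.from_index(int(i), 2)
            b = AncestralConfiguration.from_index(int(j), 2)
            assert transition_prob(a, b, 512.0, 0.07, model) == pytest.approx(
                oracle_transition(int(i), int(j), 512.0, 0.07, model), rel=1e-12)


class TestEmission:
    def test_fixed_difference_consistent_routing(self):
        # AC routes h1 to an A founder, h2 to a B founder
        ac = AncestralConfiguration(K=1, P=0, C=(0, 1), R=())
        assert emission_prob(ac, (1, 0), freqA=1.0, freqB=0.0) == 1.0

    def test_fixed_difference_impossible_routing(self):
        ac = AncestralConfiguration(K=1, P=1, C=(0, 1), R=())   # h1 -> B founder
        assert emission_prob(ac, (1, 0), freqA=1.0, freqB=0.0) == 0.0

    def test_product_of_frequencies(self):
        ac = AncestralConfiguration(K=1, P=0, C=(0, 0), R=())
        # both haplotypes from population A; observed alleles 1 and 0
        assert emission_prob(ac, (1, 0), freqA=0.8, freqB=0.5) == \
            pytest.approx(0.8 * 0.2)
        ac2 = AncestralConfiguration(K=1, P=0, C=(0, 1), R=())
        assert emission_prob(ac2, (1, 1), freqA=0.8, freqB=0.3) == \
            pytest.approx(0.24)

    def test_bad_frequency(self):
        ac = AncestralConfiguration(K=1, P=0, C=(0, 0), R=())
        with pytest.raises(ValueError):
            emission_prob(ac, (0, 0), freqA=1.2, freqB=0.0)

    def test_vector_matches_scalar(self, rng):
        for K in (1, 2):
            fA, fB = rng.uniform(0, 1, 2)
            a1, a2 = rng.integers(0, 2, 2)
            vec = emission_vector(a1, a2, fA, fB, K)
            for idx in rng.integers(0, n_states(K), 25):
                assert vec[idx] == pytest.approx(
                    oracle_emission(int(idx), a1, a2, fA, fB, K), rel=1e-12)


class TestInitDistribution:
    def test_sums_to_one(self, rng):
        for K in (1, 2, 3):
            v = init_distribution(random_model(rng, K))
            assert v.sum() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_stationary_law(self):
        # founder 1 nearly pure A: states with C[0]=1 carry (almost) no mass
        model = FounderModel(1, rateAB=[1e-10, 1e-7], rateBA=[1e-2, 1e-7])
        v = init_distribution(model)
        mass_C1_is_1 = sum(v[i] for i in range(8) if decode_ac(i, 1)[1][0] == 1)
        assert mass_C1_is_1 == pytest.approx(0.0, abs=1e-7)

    def test_uniform_product_law(self):
        model = FounderModel(1, rateAB=[1e-7, 1e-7], rateBA=[1e-7, 1e-7])
        assert init_distribution(model) == pytest.approx(np.full(8, 1 / 8))

    def test_matches_oracle(self, rng):
        model = random_model(rng, 2)
        v = init_distribution(model)
        for idx in rng.integers(0, 128, 20):
            assert v[idx] == pytest.approx(oracle_init(int(idx), model), rel=1e-12)


# ----------------------------------------------------------------------
# divide-and-conquer forward step
# ----------------------------------------------------------------------
class TestForwardStepDC:
    def test_identity_transition(self, rng):
        model = random_model(rng, 2)
        v = rng.random(n_states(2))
        out = forward_step_dc(v, d=0.0, rec_prob=0.0, model=model)
        assert out == pytest.approx(v, rel=1e-15)

    @pytest.mark.parametrize("K", [1, 2])
    def test_matches_dense_oracle(self, K, rng):
        for _ in range(10):
            model = random_model(rng, K, pp=float(rng.uniform(0, 1e-5)))
            d = float(rng.uniform(0, 1e6))
            rec = float(rng.uniform(0, 0.5))
            v = rng.random(n_states(K))
            dense = oracle_dense_T(d, rec, model) @ v
            out = forward_step_dc(v, d, rec, model)
            assert np.max(np.abs(out - dense)) <= 1e-12 * max(1.0, dense.max())

    def test_mass_conservation(self, rng):
        for K in (1, 2, 3):
            model = random_model(rng, K, pp=1e-6)
            v = rng.random(n_states(K))
            out = forward_step_dc(v, 1000.0, 0.3, model)
            assert out.sum() == pytest.approx(v.sum(), rel=1e-12)

    @pytest.mark.parametrize("K", [1, 2, 3])
    def test_complexity_nlogn(self, K, rng):
        model = random_model(rng, K)
        v = rng.random(n_states(K))
        counter = OpCounter()
        forward_step_dc(v, 100.0, 0.1, model, counter=counter)
        N, b = n_states(K), n_bits(K)
        assert counter.multiply_adds == 2 * N * b    # = 2 N log2 N
        assert counter.multiply_adds <= 2 * N * np.log2(N) < N * N

    def test_wrong_length(self, rng):
        model = random_model(rng, 2)
        with pytest.raises(ValueError):
            forward_step_dc(np.ones(8), 1.0, 0.0, model)


# ----------------------------------------------------------------------
# log-likelihood
# ----------------------------------------------------------------------
class TestLoglikelihood:
    def test_intro_worked_example(self):
        sites = SiteTable(chrom=["1"], pos_bp=[100], freqA=[1.0], freqB=[0.0],
                          gen_pos=[0.0])
        # parents pure A and pure B
        pure = FounderModel(1, rateAB=[1e-10, 1e-2], rateBA=[1e-2, 1e-10])
        p = sum(np.exp(loglikelihood(PhasedGenome([a], [b]), sites, pure,
                                     engine="numpy"))
                for a, b in ((1, 0), (0, 1)))
        assert p == pytest.approx(1.0, abs=1e-6)
        # both parents 50:50
        half = FounderModel(1, rateAB=[1e-6, 1e-6], rateBA=[1e-6, 1e-6])
        p = sum(np.exp(loglikelihood(PhasedGenome([a], [b]), sites, half,
                                     engine="numpy"))
                for a, b in ((1, 0), (0, 1)))
        assert p == pytest.approx(0.5, abs=1e-9)

    def test_path_enumeration_K1(self, rng):
        sites = random_sites(rng, 3)
        genome = random_genome(rng, 3)
        model = random_model(rng, 1, pp=1e-5)
        ll = loglikelihood(genome, sites, model, engine="numpy")
        assert ll == pytest.approx(oracle_path_enum_loglik(genome, sites, model),
                                   abs=1e-10)

    def test_path_enumeration_K2(self, rng):
        sites = random_sites(rng, 2)
        genome = random_genome(rng, 2)
        model = random_model(rng, 2, pp=1e-5)
        ll = loglikelihood(genome, sites, model, engine="numpy")
        assert ll == pytest.approx(oracle_path_enum_loglik(genome, sites, model),
                                   abs=1e-10)

    @pytest.mark.parametrize("K,n", [(1, 6), (2, 6)])
    def test_dense_forward_oracle(self, K, n, rng):
        sites = random_sites(rng, n, n_chrom=2)
        genome = random_genome(rng, n)
        model = random_model(rng, K, pp=2e-6)
        ll = loglikelihood(genome, sites, model, engine="numpy")
        assert ll == pytest.approx(oracle_dense_forward_loglik(genome, sites, model),
                                   abs=1e-10)

    def test_engines_agree(self, rng):
        sites = random_sites(rng, 120, n_chrom=3)
        genome = random_genome(rng, 120)
        for K in (1, 2):
            model = random_model(rng, K, pp=1e-5)
            for linked in (True, False):
                a = loglikelihood(genome, sites, model, engine="numpy",
                                  linked=linked)
                b = loglikelihood(genome, sites, model, engine="numba",
                                  linked=linked)
                assert a == pytest.approx(b, abs=1e-9)

    def test_conservation_uninformative_sites(self, rng):
        # freqA = freqB = 0.5 makes every emission exactly 0.25
        n = 40
        sites = random_sites(rng, n, n_chrom=2)
        sites.freqA[:] = 0.5
        sites.freqB[:] = 0.5
        genome = random_genome(rng, n)
        model = random_model(rng, 1, pp=1e-5)
        ll = loglikelihood(genome, sites, model, engine="numpy")
        assert ll == pytest.approx(n * np.log(0.25), rel=1e-12)

    def test_label_symmetry(self, rng):
        sites = random_sites(rng, 80, n_chrom=2)
        genome = random_genome(rng, 80)
        for K in (1, 2):
            model = random_model(rng, K, pp=1e-5)
            a = loglikelihood(genome, sites, model)
            b = loglikelihood(genome, sites, model.swap_halves())
            assert a == pytest.approx(b, abs=1e-10)

    def test_monotone_information(self, rng):
        # pure-A data is likelier under a pure-A model than a 50:50 model
        n = 200
        sites = random_sites(rng, n)
        sites.freqA[:] = rng.uniform(0.6, 0.95, n)
        sites.freqB[:] = rng.uniform(0.05, 0.4, n)
        h1 = (rng.random(n) < sites.freqA).astype(np.uint8)
        h2 = (rng.random(n) < sites.freqA).astype(np.uint8)
        genome = PhasedGenome(h1, h2)
        pure = FounderModel(1, rateAB=[1e-10, 1e-10], rateBA=[1e-5, 1e-5])
        half = FounderModel(1, rateAB=[1e-7, 1e-7], rateBA=[1e-7, 1e-7])
        assert loglikelihood(genome, sites, pure) >= \
            loglikelihood(genome, sites, half)

    def test_unlinked_sums_per_chromosome(self, rng):
        sites = random_sites(rng, 30, n_chrom=3)
        genome = random_genome(rng, 30)
        model = random_model(rng, 1)
        total = loglikelihood(genome, sites, model, engine="numpy", linked=False)
        parts = 0.0
        for sl in sites.chrom_slices():
            parts += loglikelihood(genome.subset(range(sl.start, sl.stop)),
                                   sites.subset(range(sl.start, sl.stop)),
                                   model, engine="numpy")
        assert total == pytest.approx(parts, abs=1e-10)

    def test_forward_scan_matches(self, rng):
        sites = random_sites(rng, 25, n_chrom=2)
        genome = random_genome(rng, 25)
        model = random_model(rng, 1)
        states = forward_scan(genome, sites, model)
        assert len(states) == 2
        for fs in states:
            assert fs.probs.sum() == pytest.approx(1.0, abs=1e-12)
        total = sum(fs.log_scale for fs in states)
        assert total == pytest.approx(
            loglikelihood(genome, sites, model, engine="numpy", linked=False),
            abs=1e-10)

    def test_errors(self, rng):
        model = random_model(rng, 1)
        sites = random_sites(rng, 5)
        with pytest.raises(ValueError):
            loglikelihood(random_genome(rng, 4), sites, model)
        bad = random_sites(rng, 5)
        bad.freqA[2] = np.nan
        with pytest.raises(ValueError):
            loglikelihood(random_genome(rng, 5), bad, model)
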