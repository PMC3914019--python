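"""Caller classes: likelihoods, single-sample, EM multi-sample, copying HMM."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcwgs import callers
from lcwgs import simulate as sim
from lcwgs._utils import ParameterError
from lcwgs.callers import (
    DiploidCopyingHMM,
    _genotype_given_templates,
    _hwe_priors,
    call_ld_aware,
    call_multi_sample,
    call_single_sample,
    estimate_frequency_em,
    genotype_likelihoods,
    hmm_posteriors,
)
from lcwgs.simulate import MISSING, PileupMatrix


def make_pileups(ref, alt):
    ref = np.atleast_2d(np.asarray(ref))
    alt = np.atleast_2d(np.asarray(alt))
    n, s = ref.shape
    return PileupMatrix(
        ref, alt, [f"S{i}" for i in range(n)],
        np.arange(1, s + 1) * 10, np.array(["A"] * s), np.array(["C"] * s),
    )


class TestGenotypeLikelihoods:
    def test_two_ref_reads_no_error(self):
        lik, pl = genotype_likelihoods(2, 0, 0.0)
        assert np.allclose(lik, [1.0, 0.25, 0.0])
        assert np.array_equal(pl, [0, 6, 255])

    def test_no_data_is_flat(self):
        lik, pl = genotype_likelihoods(0, 0, 0.01)
        assert np.allclose(lik, [1, 1, 1])
        assert np.array_equal(pl, [0, 0, 0])

    def test_balanced_reads_favor_het(self):
        _, pl = genotype_likelihoods(3, 3, 0.01)
        assert np.argmin(pl) == 1

    def test_closed_form_agreement(self):
        # direct evaluation of the three binomial formulas
        import math
        r, a, e = 5, 2, 0.02
        lik, _ = genotype_likelihoods(r, a, e)
        comb = math.comb(7, 2)
        assert np.allclose(
            lik,
            [comb * e**2 * (1 - e) ** 5, comb * 0.5**7, comb * (1 - e) ** 2 * e**5],
        )

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            genotype_likelihoods(-1, 0, 0.01)
        with pytest.raises(ParameterError):
            genotype_likelihoods(1, 1, 0.6)


class TestSingleSample:
    def test_many_alt_reads_called_hom_alt(self):
        cs = call_single_sample(make_pileups([0], [10]), base_error=0.001)
        assert cs.genotypes.genotypes[0, 0] == 2

    def test_zero_depth_is_missing(self):
        cs = call_single_sample(make_pileups([0], [0]))
        assert cs.genotypes.genotypes[0, 0] == MISSING

    def test_balanced_reads_called_het(self):
        cs = call_single_sample(make_pileups([5], [5]), base_error=0.01)
        assert cs.genotypes.genotypes[0, 0] == 1

    def test_low_confidence_call_is_missing(self):
        # single ref read: best-vs-second phred difference ~3 < threshold 4
        cs = call_single_sample(make_pileups([1], [0]), base_error=0.005)
        assert cs.genotypes.genotypes[0, 0] == MISSING

    def test_samples_independent_of_cohort(self):
        rng = np.random.default_rng(5)
        ref = rng.integers(0, 6, size=(6, 40))
        alt = rng.integers(0, 6, size=(6, 40))
        full = call_single_sample(make_pileups(ref, alt))
        sub = call_single_sample(make_pileups(ref[:3], alt[:3]))
        assert np.array_equal(full.genotypes.genotypes[:3], sub.genotypes.genotypes)


class TestFrequencyEM:
    def test_certain_genotypes_counting_limit(self):
        lik = np.array([[0, 0, 1], [0, 0, 1], [1, 0, 0]], dtype=float)
        q = estimate_frequency_em(lik)
        assert abs(q - 4 / 6) < 1e-6

    def test_all_hom_ref_gives_zero(self):
        lik = np.tile([1.0, 0.0, 0.0], (5, 1))
        assert estimate_frequency_em(lik) == 0.0

    def test_flat_likelihoods_return_initialization(self):
        lik = np.ones((4, 3))
        assert estimate_frequency_em(lik, init=0.37) == 0.37

    def test_matches_dense_grid_search(self):
        # 50 samples at 4x simulated from q = 0.3
        rng = np.random.default_rng(8)
        g = rng.binomial(2, 0.3, size=50)
        depth = rng.poisson(4.0, size=50)
        alt = rng.binomial(depth, np.where(g == 0, 0.01, np.where(g == 1, 0.5, 0.99)))
        pu = make_pileups((depth - alt)[None, :].T, alt[None, :].T)
        ll = callers._log_likelihood_matrix(pu, 0.01)[:, 0, :]
        lik = np.exp(ll - ll.max(axis=1, keepdims=True))
        q_em = estimate_frequency_em(lik, tol=1e-10)
        grid = np.linspace(0, 1, 100_001)
        logl = np.log(np.clip(_hwe_priors(grid)[None] * lik[:, None, :], 1e-300, None).sum(axis=2)).sum(axis=0)
        q_grid = grid[np.argmax(logl)]
        assert abs(q_em - q_grid) < 1e-3

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_em_never_decreases_likelihood(self, seed):
        rng = np.random.default_rng(seed)
        lik = rng.random((8, 3))
        _, history = estimate_frequency_em(lik, return_history=True)

        def loglik(q):
            return float(np.log((_hwe_priors(q) * lik).sum(axis=1)).sum())

        values = [loglik(q) for q in history]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))


class TestMultiSample:
    def test_singleton_flagged_at_zero_threshold(self):
        ref = np.concatenate([[0], np.full(99, 3)])[:, None]
        alt = np.concatenate([[1], np.zeros(99, dtype=int)])[:, None]
        cs = call_multi_sample(make_pileups(ref, alt), min_site_quality=0.0)
        assert cs.site_variant_flag[0]

    def test_all_zero_depth_flags_nothing(self):
        cs = call_multi_sample(make_pileups(np.zeros((4, 5), int), np.zeros((4, 5), int)))
        assert not cs.site_variant_flag.any()
        assert np.all(cs.genotypes.genotypes == 0)

    def test_pools_diffuse_evidence_single_misses(self):
        # five carriers holding one alt read each: no per-sample call
        # clears the single-sample quality bar, but the pooled likelihood
        # ratio is decisive
        ref = np.concatenate([np.zeros(5, int), np.full(95, 3)])[:, None]
        alt = np.concatenate([np.ones(5, int), np.zeros(95, int)])[:, None]
        pu = make_pileups(ref, alt)
        assert not call_single_sample(pu).site_variant_flag[0]
        assert call_multi_sample(pu).site_variant_flag[0]

    def test_flagged_site_always_has_a_carrier(self):
        rng = np.random.default_rng(13)
        depth = rng.poisson(2.0, size=(40, 60))
        g_true = rng.binomial(2, 0.05, size=(40, 60))
        alt = rng.binomial(depth, np.where(g_true == 0, 0.005, 0.5))
        cs = call_multi_sample(make_pileups(depth - alt, alt))
        has_alt = np.any(cs.genotypes.genotypes > 0, axis=0)
        assert np.array_equal(cs.site_variant_flag, has_alt)


def brute_force_posteriors(lik, templates, r, e):
    """Path enumeration oracle for the diploid copying model."""
    H, S = templates.shape
    m = _genotype_given_templates(e)
    states = list(itertools.product(range(H), repeat=2))

    def trans(s1, s2):
        p = 1.0
        for a, b in zip(s1, s2):
            p *= (1 - r) * (a == b) + r / H
        return p

    post = np.zeros((S, 3))
    total = 0.0
    for path in itertools.product(states, repeat=S):
        p = 1.0 / (H * H)
        for t in range(1, S):
            p *= trans(path[t - 1], path[t])
        emis = [
            np.array([m[templates[j, t], templates[k, t], g] * lik[t, g] for g in range(3)])
            for t, (j, k) in enumerate(path)
        ]
        total += p * np.prod([w.sum() for w in emis])
        for t in range(S):
            rest = np.prod([emis[u].sum() for u in range(S) if u != t])
            post[t] += p * rest * emis[t]
    return post / total


class TestCopyingHMM:
    def test_flat_likelihood_single_site_gives_template_pair_prior(self):
        post = hmm_posteriors(np.ones((1, 3)), np.array([[0], [1]], dtype=np.int8))
        assert np.allclose(post, [[0.25, 0.5, 0.25]])

    def test_unanimous_ref_templates_no_error_force_hom_ref(self):
        post = hmm_posteriors(
            np.ones((2, 3)), np.zeros((3, 2), dtype=np.int8), template_error=0.0
        )
        assert np.allclose(post[:, 0], 1.0)

    def test_empty_or_single_template_rejected(self):
        with pytest.raises(ParameterError):
            hmm_posteriors(np.ones((1, 3)), np.zeros((0, 1), dtype=np.int8))
        with pytest.raises(ParameterError):
            hmm_posteriors(np.ones((1, 3)), np.zeros((1, 1), dtype=np.int8))

    def test_site_count_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            hmm_posteriors(np.ones((3, 3)), np.zeros((2, 2), dtype=np.int8))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=15, deadline=None)
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        H = int(rng.integers(2, 5))
        S = int(rng.integers(1, 4))
        templates = rng.integers(0, 2, size=(H, S)).astype(np.int8)
        lik = rng.random((S, 3)) + 1e-3
        r = float(rng.uniform(0, 0.3))
        e = float(rng.uniform(0, 0.3))
        expected = brute_force_posteriors(lik, templates, r, e)
        got = hmm_posteriors(lik, templates, r, e)
        assert np.abs(expected - got).max() < 1e-9

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=15, deadline=None)
    def test_posteriors_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        H, S = int(rng.integers(2, 8)), int(rng.integers(1, 30))
        post = hmm_posteriors(
            rng.random((S, 3)) + 1e-6,
            rng.integers(0, 2, size=(H, S)).astype(np.int8),
            float(rng.uniform(0, 0.5)),
            float(rng.uniform(0, 0.5)),
        )
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_sampled_haplotypes_consistent_with_posterior_mean(self):
        rng = np.random.default_rng(3)
        templates = rng.integers(0, 2, size=(4, 6)).astype(np.int8)
        lik = rng.random((6, 3)) + 1e-3
        hmm = DiploidCopyingHMM(lik, templates, 0.1, 0.05)
        expected = hmm.posteriors() @ np.array([0.0, 1.0, 2.0])
        draws = np.zeros(6)
        n = 4000
        for _ in range(n):
            draws += hmm.sample_haplotype_pair(rng).sum(axis=0)
        assert np.abs(draws / n - expected).max() < 0.08


class TestLDAware:
    def test_high_depth_matches_single_sample(self):
        ped = sim.generate_pedigree(10, 2, seed=51)
        panel = sim.simulate_admixed_founder_panel(ped, 120, seed=52)
        truth = sim.gene_drop(ped, panel, seed=53)
        pu = sim.simulate_pileups(truth, np.full(truth.n_samples, 30.0), 0.001, seed=54)
        single = call_single_sample(pu, base_error=0.001).genotypes.genotypes
        ld = call_ld_aware(pu, base_error=0.001, seed=55).genotypes.genotypes
        single = np.where(single == MISSING, 0, single)
        agree = (single == ld).mean()
        assert agree >= 0.99

    def test_zero_depth_sample_imputed_from_shared_haplotype(self):
        shared = np.tile(np.array([0, 1, 1, 0, 1], dtype=np.int8), (10, 1))
        panel = sim.HaplotypePanel(
            shared, np.arange(1, 6) * 10, np.array(["A"] * 5), np.array(["C"] * 5),
            [f"S{i}" for i in range(5)],
        )
        depths = np.array([8.0, 8, 8, 8, 0])
        pu = sim.simulate_pileups(panel, depths, 0.0, seed=56)
        cs = call_ld_aware(pu, base_error=0.001, seed=57)
        assert np.array_equal(cs.genotypes.genotypes[4], [0, 2, 2, 0, 2])

    def test_deterministic_for_fixed_seed(self):
        ped = sim.generate_pedigree(8, 2, seed=61)
        panel = sim.simulate_admixed_founder_panel(ped, 80, seed=62)
        truth = sim.gene_drop(ped, panel, seed=63)
        pu = sim.simulate_pileups(truth, np.full(truth.n_samples, 3.0), 0.005, seed=64)
        a = call_ld_aware(pu, seed=99)
        b = call_ld_aware(pu, seed=99)
        assert np.array_equal(a.genotypes.genotypes, b.genotypes.genotypes)
        assert np.allclose(a.call_quality, b.call_quality)

    def test_invalid_rounds_rejected(self):
        pu = make_pileups(np.zeros((3, 4), int), np.zeros((3, 4), int))
        with pytest.raises(ParameterError):
            call_ld_aware(pu, n_rounds=0)


def test_all_callers_converge_to_truth_at_high_depth():
    ped = sim.generate_pedigree(10, 2, seed=71)
    panel = sim.simulate_admixed_founder_panel(ped, 100, seed=72)
    truth = sim.gene_drop(ped, panel, seed=73)
    pu = sim.simulate_pileups(truth, np.full(truth.n_samples, 50.0), 0.0, seed=74)
    dose = truth.haplotypes[0::2] + truth.haplotypes[1::2]
    for cs in (
        call_single_sample(pu, base_error=0.001),
        call_multi_sample(pu, base_error=0.001),
        call_ld_aware(pu, base_error=0.001, seed=75),
    ):
        g = np.where(cs.genotypes.genotypes == MISSING, 0, cs.genotypes.genotypes)
        assert (g == dose).mean() > 0.999
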