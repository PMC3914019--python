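"""Evaluation statistics: HWE exact test, marker QC, concordance, FPR,
site finding and the discovery model."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcwgs import evaluate
from lcwgs._utils import DimensionError, EmptyInputError, ParameterError
from lcwgs.callers import CallSet
from lcwgs.evaluate import (
    false_positive_rate,
    filter_markers,
    fit_discovery_model,
    frequency_comparison,
    hwe_exact_test,
    sample_concordance,
    site_finding,
)
from lcwgs.simulate import MISSING, ChipDataset, GenotypeMatrix


def hwe_oracle(n_homref, n_het, n_homalt):
    """Independent enumeration: place the alternate alleles on explicit
    allele slots, pair consecutive slots into genotypes, and tabulate the
    exact conditional distribution of heterozygote counts."""
    n = n_homref + n_het + n_homalt
    n_alt = 2 * n_homalt + n_het
    counts: dict[int, int] = {}
    for slots in itertools.combinations(range(2 * n), n_alt):
        chosen = set(slots)
        hets = sum(
            1 for i in range(n) if (2 * i in chosen) != (2 * i + 1 in chosen)
        )
        counts[hets] = counts.get(hets, 0) + 1
    total = math.comb(2 * n, n_alt)
    p_obs = Fraction(counts.get(n_het, 0), total)
    if p_obs == 0:
        return 1.0
    p = sum(Fraction(c, total) for c in counts.values() if Fraction(c, total) <= p_obs)
    return float(p)


class TestHWEExactTest:
    def test_monomorphic_site_gives_one(self):
        assert hwe_exact_test(50, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 50) == 1.0

    def test_balanced_configuration_matches_monte_carlo_pairing(self):
        # (25, 50, 25) is exact HWE proportions; enumeration over allele
        # subsets is infeasible at 2N = 200, so the independent check is a
        # Monte-Carlo pairing of the 200 alleles
        p = hwe_exact_test(25, 50, 25)
        rng = np.random.default_rng(0)
        alleles = np.array([1] * 100 + [0] * 100)
        n_draws = 20_000
        obs_prob = None
        hits = 0
        # conditional probability of each het count, estimated by shuffling
        from collections import Counter

        het_counts = Counter()
        for _ in range(n_draws):
            rng.shuffle(alleles)
            het_counts[int((alleles[0::2] != alleles[1::2]).sum())] += 1
        p_obs_hat = het_counts[50] / n_draws
        p_hat = sum(c for h, c in het_counts.items()
                    if het_counts[h] / n_draws <= p_obs_hat) / n_draws
        assert p == pytest.approx(p_hat, abs=4 * np.sqrt(p_hat * (1 - p_hat) / n_draws) + 0.02)

    def test_all_het_extreme_matches_enumeration_and_is_tiny(self):
        assert hwe_exact_test(0, 10, 0) == pytest.approx(hwe_oracle(0, 10, 0), abs=1e-18)
        assert hwe_exact_test(0, 100, 0) < 1e-10  # removed by the p < 1e-10 filter

    def test_spot_checks_against_enumeration(self):
        for cfg in [(3, 1, 2), (0, 5, 0), (4, 0, 4), (1, 2, 3), (7, 2, 1)]:
            assert hwe_exact_test(*cfg) == pytest.approx(hwe_oracle(*cfg), abs=1e-15)

    def test_all_zero_rejected(self):
        with pytest.raises(ParameterError):
            hwe_exact_test(0, 0, 0)


class TestFilterMarkers:
    def test_removes_exactly_the_planted_artifacts(self, artifact_chip):
        chip, calls, markers = artifact_chip
        qc = filter_markers(chip, calls)
        assert list(qc.flipped_removed) == [markers["flip"]]
        assert list(qc.dup_discordant_removed) == [markers["dup_bad"]]
        assert list(qc.hwe_removed) == [markers["hwe"]]
        assert qc.surviving_mask.sum() == chip.genotypes.n_sites - 3

    def test_three_discordant_pairs_is_kept(self, artifact_chip):
        chip, calls, markers = artifact_chip
        qc = filter_markers(chip, calls)
        assert markers["dup_ok"] not in set(qc.dup_discordant_removed)
        assert qc.surviving_mask[markers["dup_ok"]]

    def test_removal_reasons_recorded_and_disjoint(self, artifact_chip):
        chip, calls, _ = artifact_chip
        qc = filter_markers(chip, calls)
        removed = set(qc.flipped_removed) | set(qc.dup_discordant_removed) | set(qc.hwe_removed)
        assert set(qc.removal_reason) == removed
        assert not (removed & set(qc.surviving_markers))

    def test_clean_chip_removes_nothing(self, artifact_chip):
        chip, calls, markers = artifact_chip
        keep = [
            j for j in range(chip.genotypes.n_sites)
            if j not in (markers["flip"], markers["dup_bad"], markers["hwe"])
        ]
        gm = GenotypeMatrix(
            chip.genotypes.genotypes[:, keep],
            list(chip.genotypes.sample_ids),
            chip.genotypes.positions[keep],
            chip.genotypes.ref_allele[keep],
            chip.genotypes.alt_allele[keep],
        )
        clean = ChipDataset(gm, np.zeros(len(keep), bool), chip.duplicate_pairs)
        call_gm = GenotypeMatrix(
            calls.genotypes.genotypes[:, keep],
            list(calls.sample_ids),
            gm.positions.copy(),
            gm.ref_allele.copy(),
            gm.alt_allele.copy(),
        )
        flag = np.any(call_gm.genotypes > 0, axis=0)
        clean_calls = CallSet(call_gm, flag, np.zeros(len(keep)))
        qc = filter_markers(clean, clean_calls)
        assert qc.surviving_mask.all()

    def test_no_overlap_raises(self, artifact_chip):
        chip, calls, _ = artifact_chip
        calls.genotypes.positions = calls.genotypes.positions + 7  # misalign
        with pytest.raises(EmptyInputError):
            filter_markers(chip, calls)


def simple_pair(chip_g, call_g, positions=None):
    """Build an aligned (chip, calls, qc) triple from two genotype arrays."""
    chip_g = np.asarray(chip_g, dtype=np.int8)
    call_g = np.asarray(call_g, dtype=np.int8)
    n, s = chip_g.shape
    if positions is None:
        positions = np.arange(1, s + 1) * 10
    ids = [f"S{i}" for i in range(n)]
    ref = np.array(["A"] * s)
    alt = np.array(["C"] * s)
    chip = ChipDataset(
        GenotypeMatrix(chip_g, ids, positions, ref, alt), np.zeros(s, bool), []
    )
    flag = np.any((call_g > 0) & (call_g != MISSING), axis=0)
    calls = CallSet(
        GenotypeMatrix(call_g, ids, positions, ref, alt), flag, np.zeros(s)
    )
    qc = filter_markers(chip, calls, flip_min_carriers=10**9)
    return chip, calls, qc


class TestSampleConcordance:
    def test_three_of_four_variant_sites_match(self):
        chip_g = [[1, 1, 2, 1, 0]]
        call_g = [[1, 1, 2, 0, 0]]
        chip, calls, qc = simple_pair(chip_g, call_g)
        df = sample_concordance(calls, chip, qc)
        assert df.n_variant.iloc[0] == 4
        assert df.concordance.iloc[0] == 0.75

    def test_missing_call_at_het_site_counts_as_hom_ref(self):
        chip, calls, qc = simple_pair([[1, 1]], [[MISSING, 1]])
        df = sample_concordance(calls, chip, qc)
        assert df.n_variant.iloc[0] == 2 and df.n_match.iloc[0] == 1

    def test_identical_calls_give_perfect_concordance(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(6, 30))
        g[:, 0] = [0, 1, 2, 1, 0, 1]  # guarantee polymorphism
        chip, calls, qc = simple_pair(g, g.copy())
        df = sample_concordance(calls, chip, qc)
        assert np.allclose(df.concordance, 1.0)

    def test_chip_missing_sites_excluded(self):
        chip, calls, qc = simple_pair([[1, MISSING, 2]], [[1, 2, 2]])
        df = sample_concordance(calls, chip, qc)
        assert df.n_variant.iloc[0] == 2 and df.concordance.iloc[0] == 1.0

    def test_invariant_to_marker_and_sample_order(self):
        rng = np.random.default_rng(3)
        chip_g = rng.integers(0, 3, size=(5, 20))
        call_g = rng.integers(0, 3, size=(5, 20))
        chip, calls, qc = simple_pair(chip_g, call_g)
        base = sample_concordance(calls, chip, qc).set_index("sample_id").concordance

        perm = rng.permutation(20)
        pos = np.arange(1, 21) * 10
        order = np.argsort(pos[perm])
        chip2, calls2, qc2 = simple_pair(
            chip_g[:, perm][:, order], call_g[:, perm][:, order], pos[perm][order]
        )
        again = sample_concordance(calls2, chip2, qc2).set_index("sample_id").concordance
        assert np.allclose(base, again)


class TestFalsePositiveRate:
    def test_one_in_ten_alt_calls_wrong(self):
        chip_g = np.array([[0] + [1] * 9])
        call_g = np.ones((1, 10), dtype=int)
        chip, calls, qc = simple_pair(chip_g, call_g)
        fpr = false_positive_rate(calls, chip, qc)
        assert fpr.fpr.iloc[0] == pytest.approx(0.1)

    def test_no_alt_calls_is_undefined_not_zero(self):
        chip, calls, qc = simple_pair([[1, 0, 2]], [[0, 0, 0]])
        fpr = false_positive_rate(calls, chip, qc)
        assert np.isnan(fpr.fpr.iloc[0])

    def test_calls_equal_chip_gives_zero(self):
        chip, calls, qc = simple_pair([[1, 0, 2, 1]], [[1, 0, 2, 1]])
        fpr = false_positive_rate(calls, chip, qc)
        assert fpr.fpr.iloc[0] == 0.0


class TestSiteFinding:
    def test_wrong_zygosity_still_counts_as_found(self):
        # chip singleton (one het); caller emits hom-alt in another sample
        chip_g = [[1, 1], [0, 1], [0, 1], [0, 1]]
        call_g = [[0, 1], [2, 1], [0, 1], [0, 1]]
        chip, calls, qc = simple_pair(chip_g, call_g)
        table = evaluate.site_discovery_table(calls, chip, qc)
        assert bool(table[table.mac == 1].found.iloc[0])

    def test_flag_everything_gives_unit_fractions(self):
        rng = np.random.default_rng(4)
        chip_g = rng.integers(0, 3, size=(20, 50))
        call_g = np.ones((20, 50), dtype=int)
        chip, calls, qc = simple_pair(chip_g, call_g)
        df = site_finding(calls, chip, qc)
        filled = df.dropna(subset=["found_fraction"])
        assert (filled.found_fraction == 1.0).all()

    def test_empty_bin_reports_nan(self):
        chip_g = [[2, 2], [2, 2], [0, 2], [0, 2]]  # no singletons
        call_g = [[2, 2], [2, 2], [0, 2], [0, 2]]
        chip, calls, qc = simple_pair(chip_g, call_g)
        df = site_finding(calls, chip, qc)
        assert np.isnan(df[df.bin == "MAC=1"].found_fraction.iloc[0])


class TestDiscoveryModel:
    def test_model_closed_form(self):
        assert 1 - (1 - 0.2) ** 3 == pytest.approx(0.488)

    def test_bernoulli_limit_for_singletons(self):
        found = np.array([True] * 50 + [False] * 50)
        p = fit_discovery_model(found, np.ones(100))
        assert p == pytest.approx(0.5, abs=1e-4)

    def test_recovers_simulation_parameter(self):
        rng = np.random.default_rng(6)
        f = rng.integers(1, 21, size=5000)
        found = rng.random(5000) < 1 - (1 - 0.3) ** f
        p = fit_discovery_model(found, f)
        assert 0.27 < p < 0.33

    def test_all_zero_carriers_rejected(self):
        with pytest.raises(EmptyInputError):
            fit_discovery_model(np.array([True, False]), np.zeros(2))


class TestFrequencyComparison:
    def test_identical_vectors_concentrate_on_diagonal(self):
        f = np.linspace(0.01, 0.99, 37)
        cmp_ = frequency_comparison(f, f, grid=20)
        diag = np.trace(cmp_.hist2d)
        assert diag == cmp_.hist2d.sum() == 37
        mid = len(cmp_.diff_counts) // 2
        assert cmp_.diff_counts[mid - 1 : mid + 1].sum() == 37

    def test_mass_conservation(self):
        rng = np.random.default_rng(7)
        a, b = rng.random(500), rng.random(500)
        cmp_ = frequency_comparison(a, b, grid=30)
        assert cmp_.hist2d.sum() == 500 == cmp_.diff_counts.sum()

    def test_independent_populations_have_tails(self):
        rng = np.random.default_rng(8)
        a, b = rng.random(2000), rng.random(2000)
        cmp_ = frequency_comparison(a, b, grid=10)
        big_diff = np.abs((cmp_.diff_edges[:-1] + cmp_.diff_edges[1:]) / 2) > 0.3
        assert cmp_.diff_counts[big_diff].sum() > 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(DimensionError):
            frequency_comparison(np.zeros(3), np.zeros(4))


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=25, deadline=None)
def test_concordance_and_fpr_bounded(seed):
    rng = np.random.default_rng(seed)
    n, s = int(rng.integers(2, 8)), int(rng.integers(2, 30))
    chip_g = rng.integers(-1, 3, size=(n, s))
    call_g = rng.integers(-1, 3, size=(n, s))
    if not np.any((chip_g > 0) | (call_g > 0)):
        chip_g[0, 0] = 1
    chip, calls, qc = simple_pair(chip_g, call_g)
    df = sample_concordance(calls, chip, qc)
    ok = df.concordance.dropna()
    assert ((ok >= 0) & (ok <= 1)).all()
    okf = df.fpr.dropna()
    assert ((okf >= 0) & (okf <= 1)).all()
    assert (df.n_match <= df.n_variant).all()
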