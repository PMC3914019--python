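"""Synthetic cohort generation.

Everything downstream (callers, evaluation, kinship) consumes the objects
produced here: a multi-generation pedigree with optional two-population
admixture, founder haplotypes carrying distance-decaying linkage
disequilibrium, gene-dropped truth genotypes, Poisson read pileups, and an
exome-chip-style genotype set with the artifacts (A/B allele flips,
duplicate samples, missingness, monomorphic markers) that the QC filters
are designed to catch.

The LD model is deliberately minimal: founder haplotypes are mosaics of a
small panel of seed haplotypes, switching seeds between adjacent sites with
a fixed probability, plus per-site mutation flips.  This yields tunable,
distance-decaying r^2 without coalescent machinery — which is all the
haplotype-copying caller needs to exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import DimensionError, ParameterError, check, check_probability

MISSING = -1  # missing genotype sentinel in all dosage matrices

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PedigreeTable:
    """Individuals with parent links; parents always precede children.

    ``sex`` uses PLINK coding (1 male, 2 female, 0 unknown).
    ``founder_population`` is 'A' or 'B' for founders, None for non-founders.
    """

    individual_id: list[str]
    father_id: list[str | None]
    mother_id: list[str | None]
    sex: np.ndarray
    founder_population: list[str | None]

    def __post_init__(self) -> None:
        n = len(self.individual_id)
        self.sex = np.asarray(self.sex, dtype=np.int64)
        if not (len(self.father_id) == len(self.mother_id) == len(self.sex) == n):
            raise DimensionError("pedigree columns have unequal lengths")
        seen: dict[str, int] = {}
        for i, (iid, fa, mo) in enumerate(
            zip(self.individual_id, self.father_id, self.mother_id)
        ):
            if iid in seen:
                raise ParameterError(f"duplicate individual id {iid!r}")
            if (fa is None) != (mo is None):
                raise ParameterError(f"{iid!r}: both parents present or both absent")
            if fa is not None:
                if fa not in seen or mo not in seen:
                    raise ParameterError(
                        f"{iid!r}: parents must precede children in storage order"
                    )
            seen[iid] = i
        self._index = seen

    @property
    def n(self) -> int:
        return len(self.individual_id)

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    @property
    def is_founder(self) -> np.ndarray:
        return np.array([f is None for f in self.father_id])

    @property
    def founder_ids(self) -> list[str]:
        return [i for i, f in zip(self.individual_id, self.father_id) if f is None]


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes, two per individual.

    ``haplotypes`` has shape (2 * n_samples, n_sites) with 0 = reference
    allele, 1 = alternate; haplotypes 2i and 2i+1 belong to sample i.
    Positions are 1-based and strictly increasing (single chromosome).
    """

    haplotypes: np.ndarray
    site_positions: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.site_positions = np.asarray(self.site_positions, dtype=np.int64)
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise DimensionError("need exactly two haplotypes per sample")
        if self.haplotypes.shape[1] != self.site_positions.shape[0]:
            raise DimensionError("haplotype and position site counts differ")
        if np.any(np.diff(self.site_positions) <= 0):
            raise ParameterError("site positions must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def genotypes(self) -> "GenotypeMatrix":
        dose = self.haplotypes[0::2] + self.haplotypes[1::2]
        return GenotypeMatrix(
            genotypes=dose.astype(np.int8),
            sample_ids=list(self.sample_ids),
            positions=self.site_positions.copy(),
            ref_allele=self.ref_allele.copy(),
            alt_allele=self.alt_allele.copy(),
        )

    def subset_samples(self, sample_ids: list[str]) -> "HaplotypePanel":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        rows = np.array([[2 * i, 2 * i + 1] for i in idx]).ravel()
        return HaplotypePanel(
            haplotypes=self.haplotypes[rows].copy(),
            site_positions=self.site_positions.copy(),
            ref_allele=self.ref_allele.copy(),
            alt_allele=self.alt_allele.copy(),
            sample_ids=list(sample_ids),
        )


@dataclass
class GenotypeMatrix:
    """Samples x sites alternate-allele dosages {0,1,2}, -1 = missing."""

    genotypes: np.ndarray
    sample_ids: list[str]
    positions: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.genotypes.shape != (len(self.sample_ids), len(self.positions)):
            raise DimensionError("genotype matrix shape mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def allele_frequencies(self) -> np.ndarray:
        """Per-site alternate-allele frequency over non-missing genotypes."""
        obs = self.genotypes != MISSING
        alt = np.where(obs, self.genotypes, 0).astype(np.int64).sum(axis=0)
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
        return freq.astype(float)

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return GenotypeMatrix(
            genotypes=self.genotypes[idx].copy(),
            sample_ids=list(sample_ids),
            positions=self.positions.copy(),
            ref_allele=self.ref_allele.copy(),
            alt_allele=self.alt_allele.copy(),
        )


@dataclass
class PileupMatrix:
    """Per-sample per-site reference/alternate read counts.

    The only sequencing evidence the callers ever see; depth of coverage for
    a sample is the mean of (ref_count + alt_count) over sites, mirroring
    mapped-bases-over-genome-length at per-site resolution.
    """

    ref_count: np.ndarray
    alt_count: np.ndarray
    sample_ids: list[str]
    positions: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray

    def __post_init__(self) -> None:
        self.ref_count = np.asarray(self.ref_count, dtype=np.int32)
        self.alt_count = np.asarray(self.alt_count, dtype=np.int32)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.ref_count.shape != self.alt_count.shape:
            raise DimensionError("ref/alt count shapes differ")
        if self.ref_count.shape != (len(self.sample_ids), len(self.positions)):
            raise DimensionError("pileup matrix shape mismatch")
        if np.any(self.ref_count < 0) or np.any(self.alt_count < 0):
            raise ParameterError("read counts must be non-negative")

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    @property
    def mean_depth_per_sample(self) -> np.ndarray:
        return self.depth.mean(axis=1)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass
class ChipDataset:
    """Exome-chip-style genotype set, including its artifacts.

    Flipped markers store 2-g for every non-missing genotype (A/B allele
    reversal); duplicate samples are independent re-genotypings of an
    original sample; the monomorphic mask records markers with no alternate
    allele observed cohort-wide.
    """

    genotypes: GenotypeMatrix
    flipped_mask: np.ndarray
    duplicate_pairs: list[tuple[str, str]]
    monomorphic_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.flipped_mask = np.asarray(self.flipped_mask, dtype=bool)
        if self.flipped_mask.shape[0] != self.genotypes.n_sites:
            raise DimensionError("flipped_mask length mismatch")
        ids = set(self.genotypes.sample_ids)
        for a, b in self.duplicate_pairs:
            if a not in ids or b not in ids:
                raise ParameterError(f"duplicate pair ({a!r}, {b!r}) references unknown sample")
        if self.monomorphic_mask is None:
            self.monomorphic_mask = compute_monomorphic_mask(self.genotypes)
        self.monomorphic_mask = np.asarray(self.monomorphic_mask, dtype=bool)


def compute_monomorphic_mask(gm: GenotypeMatrix) -> np.ndarray:
    """Markers at which no alternate allele is observed among non-missing calls."""
    g = gm.genotypes
    return ~np.any((g > 0) & (g != MISSING), axis=0)


# ---------------------------------------------------------------------------
# pedigree generation
# ---------------------------------------------------------------------------


def _zero_truncated_poisson(rng: np.random.Generator, lam: float) -> int:
    # couples always have >= 1 child so lineages persist at desk scale
    k = int(rng.poisson(lam))
    while k == 0:
        k = int(rng.poisson(lam))
    return k


def generate_pedigree(
    n_founders: int,
    n_generations: int,
    mean_offspring: float = 2.5,
    admixture_fraction: float = 0.0,
    seed: int = 0,
    second_union_prob: float = 0.3,
) -> PedigreeTable:
    """Simulate a multi-generation pedigree with optional admixture.

    Founders form generation 1 with alternating sexes; each later
    generation pairs the previous generation's unmatched males and females
    at random and draws a zero-truncated Poisson number of children per
    couple.  With probability ``second_union_prob`` a leftover unmatched
    individual forms a second union with an already-matched partner,
    creating half-sib and avuncular structures.  A fraction
    ``admixture_fraction`` of founders is labelled population B.
    """
    check(n_founders >= 2, "n_founders must be >= 2")
    check(n_generations >= 1, "n_generations must be >= 1")
    check(mean_offspring > 0, "mean_offspring must be positive")
    check_probability(admixture_fraction, "admixture_fraction")
    rng = np.random.default_rng(seed)

    ids: list[str] = []
    fathers: list[str | None] = []
    mothers: list[str | None] = []
    sexes: list[int] = []
    pops: list[str | None] = []

    n_b = int(round(admixture_fraction * n_founders))
    b_idx = set(rng.choice(n_founders, size=n_b, replace=False).tolist())
    for i in range(n_founders):
        ids.append(f"G1-{i + 1:03d}")
        fathers.append(None)
        mothers.append(None)
        sexes.append(1 if i % 2 == 0 else 2)
        pops.append("B" if i in b_idx else "A")

    prev_gen = list(range(n_founders))
    counter = n_founders
    for gen in range(2, n_generations + 1):
        males = [i for i in prev_gen if sexes[i] == 1]
        females = [i for i in prev_gen if sexes[i] == 2]
        rng.shuffle(males)
        rng.shuffle(females)
        n_pairs = min(len(males), len(females))
        couples = list(zip(males[:n_pairs], females[:n_pairs]))
        leftovers = males[n_pairs:] + females[n_pairs:]
        for solo in leftovers:
            if rng.random() < second_union_prob and couples:
                pool = females if sexes[solo] == 1 else males
                pool = [p for p in pool[:n_pairs] if p != solo]
                if pool:
                    partner = pool[int(rng.integers(len(pool)))]
                    pair = (solo, partner) if sexes[solo] == 1 else (partner, solo)
                    couples.append(pair)
        if not couples:
            break
        this_gen: list[int] = []
        for fa, mo in couples:
            for _ in range(_zero_truncated_poisson(rng, mean_offspring)):
                counter += 1
                ids.append(f"G{gen}-{counter:03d}")
                fathers.append(ids[fa])
                mothers.append(ids[mo])
                sexes.append(int(rng.integers(1, 3)))
                pops.append(None)
                this_gen.append(len(ids) - 1)
        prev_gen = this_gen

    return PedigreeTable(ids, fathers, mothers, np.array(sexes), pops)


# ---------------------------------------------------------------------------
# founder haplotypes with LD
# ---------------------------------------------------------------------------


def _draw_site_metadata(
    n_sites: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    positions = np.cumsum(rng.integers(500, 1500, size=n_sites)).astype(np.int64)
    ref = _BASES[rng.integers(0, 4, size=n_sites)]
    shift = rng.integers(1, 4, size=n_sites)
    alt = _BASES[(np.searchsorted(_BASES, ref) + shift) % 4]
    return positions, ref, alt


def simulate_founder_haplotypes(
    n_sites: int,
    n_founders: int,
    n_seed_haplotypes: int = 10,
    switch_rate: float = 0.02,
    mutation_rate: float = 0.003,
    seed: int = 0,
    site_freqs: np.ndarray | None = None,
    positions: np.ndarray | None = None,
    ref_allele: np.ndarray | None = None,
    alt_allele: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
) -> HaplotypePanel:
    """Founder haplotypes as mosaics of a small seed-haplotype panel.

    Each founder haplotype starts on a uniformly chosen seed haplotype and
    switches to a fresh uniform seed between adjacent sites with probability
    ``switch_rate``; each allele is then flipped independently with
    probability ``mutation_rate``.  Adjacent-site LD (r^2) decays with
    inter-site index distance in expectation.

    ``site_freqs`` fixes the per-site allele frequency of the seed panel
    (used to give two admixed populations correlated but offset spectra);
    if omitted, frequencies are drawn from a rare-skewed Beta(0.5, 1.5).
    """
    check(n_seed_haplotypes >= 2, "n_seed_haplotypes must be >= 2")
    check(n_sites >= 1, "n_sites must be >= 1")
    check(n_founders >= 1, "n_founders must be >= 1")
    check_probability(switch_rate, "switch_rate")
    check_probability(mutation_rate, "mutation_rate")
    rng = np.random.default_rng(seed)

    if site_freqs is None:
        site_freqs = rng.beta(0.5, 1.5, size=n_sites)
    site_freqs = np.asarray(site_freqs, dtype=float)
    check(site_freqs.shape == (n_sites,), "site_freqs length mismatch")

    seeds = (rng.random((n_seed_haplotypes, n_sites)) < site_freqs).astype(np.int8)

    n_hap = 2 * n_founders
    state = np.empty((n_hap, n_sites), dtype=np.int64)
    state[:, 0] = rng.integers(0, n_seed_haplotypes, size=n_hap)
    switches = rng.random((n_hap, n_sites - 1)) < switch_rate
    fresh = rng.integers(0, n_seed_haplotypes, size=(n_hap, n_sites - 1))
    for s in range(1, n_sites):
        state[:, s] = np.where(switches[:, s - 1], fresh[:, s - 1], state[:, s - 1])
    haps = seeds[state, np.arange(n_sites)]
    flips = rng.random((n_hap, n_sites)) < mutation_rate
    haps = np.where(flips, 1 - haps, haps).astype(np.int8)

    if positions is None:
        positions, ref_allele, alt_allele = _draw_site_metadata(n_sites, rng)
    if sample_ids is None:
        sample_ids = [f"F{i + 1:03d}" for i in range(n_founders)]
    return HaplotypePanel(haps, positions, np.asarray(ref_allele), np.asarray(alt_allele), sample_ids)


def simulate_admixed_founder_panel(
    pedigree: PedigreeTable,
    n_sites: int,
    n_seed_haplotypes: int = 10,
    switch_rate: float = 0.02,
    mutation_rate: float = 0.003,
    freq_offset_scale: float = 0.1,
    min_minor_count: int = 1,
    seed: int = 0,
) -> HaplotypePanel:
    """Founder panel for a pedigree with population-A and -B founders.

    The two populations get independent seed panels over the same sites;
    population B's per-site frequencies are the A frequencies perturbed by
    Laplace noise of scale ``freq_offset_scale`` (wide-tailed
    cross-population differences).  With ``min_minor_count`` >= 1, sites
    monomorphic across all founder haplotypes have their mutation layer
    redrawn (bounded rejection; a forced single-haplotype toggle as a last
    resort) so every site is polymorphic among founders.
    """
    rng = np.random.default_rng(seed)
    founders = pedigree.founder_ids
    pops = [pedigree.founder_population[pedigree.index_of(f)] for f in founders]
    freqs_a = rng.beta(0.5, 1.5, size=n_sites)
    freqs_b = np.clip(freqs_a + rng.laplace(0.0, freq_offset_scale, size=n_sites), 0.0, 1.0)
    positions, ref, alt = _draw_site_metadata(n_sites, rng)

    panels: dict[str, HaplotypePanel] = {}
    for pop, freqs in (("A", freqs_a), ("B", freqs_b)):
        n_pop = sum(p == pop for p in pops)
        if n_pop == 0:
            continue
        panels[pop] = simulate_founder_haplotypes(
            n_sites,
            n_pop,
            n_seed_haplotypes=n_seed_haplotypes,
            switch_rate=switch_rate,
            mutation_rate=mutation_rate,
            seed=int(rng.integers(2**31)),
            site_freqs=freqs,
            positions=positions,
            ref_allele=ref,
            alt_allele=alt,
        )

    haps = np.empty((2 * len(founders), n_sites), dtype=np.int8)
    cursor = {pop: 0 for pop in panels}
    for i, pop in enumerate(pops):
        j = cursor[pop]
        haps[2 * i : 2 * i + 2] = panels[pop].haplotypes[2 * j : 2 * j + 2]
        cursor[pop] += 1

    if min_minor_count >= 1:
        for _ in range(20):
            mac = haps.sum(axis=0)
            bad = np.flatnonzero((mac < min_minor_count) | (mac > haps.shape[0] - min_minor_count))
            if bad.size == 0:
                break
            redraw = rng.random((haps.shape[0], bad.size)) < max(mutation_rate, 0.01)
            haps[:, bad] = np.where(redraw, 1 - haps[:, bad], haps[:, bad])
        mac = haps.sum(axis=0)
        bad = np.flatnonzero((mac < min_minor_count) | (mac > haps.shape[0] - min_minor_count))
        for s in bad:  # last resort: toggle one random haplotype
            h = int(rng.integers(haps.shape[0]))
            haps[h, s] = 1 - haps[h, s]

    return HaplotypePanel(haps, positions, ref, alt, list(founders))


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------


def _gamete(
    hap_a: np.ndarray, hap_b: np.ndarray, recomb_rate: float, rng: np.random.Generator
) -> np.ndarray:
    n_sites = hap_a.shape[0]
    start = int(rng.integers(2))
    if n_sites == 1:
        path = np.array([start])
    else:
        crossovers = rng.random(n_sites - 1) < recomb_rate
        path = (start + np.concatenate([[0], np.cumsum(crossovers)])) % 2
    return np.where(path == 0, hap_a, hap_b).astype(np.int8)


def gene_drop(
    pedigree: PedigreeTable,
    founder_panel: HaplotypePanel,
    recomb_rate: float = 0.01,
    seed: int = 0,
) -> HaplotypePanel:
    """Drop founder haplotypes through the pedigree.

    Each non-founder receives one recombinant gamete per parent (template
    switching between the parent's two haplotypes at ``recomb_rate`` per
    adjacent-site interval).  Founder haplotypes pass through unchanged; no
    mutation is introduced during the drop.
    """
    check_probability(recomb_rate, "recomb_rate")
    founders = pedigree.founder_ids
    if founder_panel.n_samples != len(founders):
        raise DimensionError(
            f"founder panel has {founder_panel.n_samples} samples, "
            f"pedigree has {len(founders)} founders"
        )
    rng = np.random.default_rng(seed)
    n_sites = founder_panel.n_sites
    haps = np.zeros((2 * pedigree.n, n_sites), dtype=np.int8)
    founder_row = {f: i for i, f in enumerate(founders)}
    for i, iid in enumerate(pedigree.individual_id):
        fa, mo = pedigree.father_id[i], pedigree.mother_id[i]
        if fa is None:
            j = founder_row[iid]
            haps[2 * i : 2 * i + 2] = founder_panel.haplotypes[2 * j : 2 * j + 2]
        else:
            pf, pm = pedigree.index_of(fa), pedigree.index_of(mo)
            haps[2 * i] = _gamete(haps[2 * pf], haps[2 * pf + 1], recomb_rate, rng)
            haps[2 * i + 1] = _gamete(haps[2 * pm], haps[2 * pm + 1], recomb_rate, rng)
    return HaplotypePanel(
        haps,
        founder_panel.site_positions.copy(),
        founder_panel.ref_allele.copy(),
        founder_panel.alt_allele.copy(),
        list(pedigree.individual_id),
    )


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------


def simulate_pileups(
    truth: HaplotypePanel,
    mean_depths: np.ndarray,
    base_error: float = 0.005,
    seed: int = 0,
) -> PileupMatrix:
    """Poisson read pileups over the truth haplotypes.

    Per sample-site the read total is Poisson(mean depth of that sample);
    each read reports the allele of a uniformly chosen one of the sample's
    two haplotypes, flipped with probability ``base_error``.
    """
    check(0.0 <= base_error < 0.5, "base_error must be in [0, 0.5)")
    mean_depths = np.asarray(mean_depths, dtype=float)
    if mean_depths.shape != (truth.n_samples,):
        raise DimensionError("mean_depths must have one entry per sample")
    check(np.all(mean_depths >= 0), "mean depths must be non-negative")
    rng = np.random.default_rng(seed)

    dose = truth.haplotypes[0::2] + truth.haplotypes[1::2]  # (n, s) in {0,1,2}
    n = rng.poisson(mean_depths[:, None], size=dose.shape)
    # reads drawn from a uniformly chosen haplotype: alt-template reads are
    # Binomial(n, dose/2); sequencing error then flips each read independently
    k_alt_template = rng.binomial(n, dose / 2.0)
    alt = rng.binomial(k_alt_template, 1.0 - base_error) + rng.binomial(
        n - k_alt_template, base_error
    )
    return PileupMatrix(
        ref_count=n - alt,
        alt_count=alt,
        sample_ids=list(truth.sample_ids),
        positions=truth.site_positions.copy(),
        ref_allele=truth.ref_allele.copy(),
        alt_allele=truth.alt_allele.copy(),
    )


# ---------------------------------------------------------------------------
# chip genotyping
# ---------------------------------------------------------------------------


def _genotype_with_error(
    g_true: np.ndarray, error: float, missing_rate: float, rng: np.random.Generator
) -> np.ndarray:
    g = g_true.copy()
    if error > 0:
        err = rng.random(g.shape) < error
        # symmetric error: replace by one of the two other genotypes uniformly
        shift = rng.integers(1, 3, size=g.shape)
        g = np.where(err, (g + shift) % 3, g).astype(np.int8)
    if missing_rate > 0:
        g = np.where(rng.random(g.shape) < missing_rate, MISSING, g).astype(np.int8)
    return g


def simulate_chip(
    truth: HaplotypePanel,
    marker_subset: np.ndarray,
    genotyping_error: float = 0.001,
    missing_rate: float = 0.005,
    flip_fraction: float = 0.005,
    n_duplicates: int = 5,
    seed: int = 0,
) -> ChipDataset:
    """Array genotypes at a marker subset, with chip artifacts.

    Truth genotypes at the marker sites receive symmetric genotyping error
    and missingness; a Bernoulli(``flip_fraction``) subset of the markers
    that are non-monomorphic in the truth has its A/B alleles reversed
    (g -> 2-g for every non-missing genotype); ``n_duplicates`` samples are
    re-genotyped independently and appended with a ``_dup`` suffix.
    """
    check_probability(genotyping_error, "genotyping_error")
    check_probability(missing_rate, "missing_rate")
    check_probability(flip_fraction, "flip_fraction")
    marker_subset = np.asarray(marker_subset, dtype=np.int64)
    check(
        marker_subset.size > 0
        and marker_subset.min() >= 0
        and marker_subset.max() < truth.n_sites,
        "marker_subset must index panel sites",
    )
    check(n_duplicates <= truth.n_samples, "n_duplicates cannot exceed sample count")
    rng = np.random.default_rng(seed)

    dose = (truth.haplotypes[0::2] + truth.haplotypes[1::2]).astype(np.int8)
    g_true = dose[:, marker_subset]
    n_samples, n_markers = g_true.shape

    truth_nonmono = np.any(g_true > 0, axis=0)
    flipped = truth_nonmono & (rng.random(n_markers) < flip_fraction)

    g_chip = _genotype_with_error(g_true, genotyping_error, missing_rate, rng)

    dup_idx = rng.choice(n_samples, size=n_duplicates, replace=False)
    g_dup = _genotype_with_error(
        g_true[dup_idx], genotyping_error, missing_rate, rng
    )

    genotypes = np.vstack([g_chip, g_dup])
    flip_cols = np.flatnonzero(flipped)
    nonmiss = genotypes[:, flip_cols] != MISSING
    genotypes[:, flip_cols] = np.where(
        nonmiss, 2 - genotypes[:, flip_cols], MISSING
    ).astype(np.int8)

    sample_ids = list(truth.sample_ids)
    dup_ids = [f"{truth.sample_ids[i]}_dup" for i in dup_idx]
    pairs = [(truth.sample_ids[i], d) for i, d in zip(dup_idx, dup_ids)]

    gm = GenotypeMatrix(
        genotypes=genotypes,
        sample_ids=sample_ids + dup_ids,
        positions=truth.site_positions[marker_subset].copy(),
        ref_allele=truth.ref_allele[marker_subset].copy(),
        alt_allele=truth.alt_allele[marker_subset].copy(),
    )
    return ChipDataset(genotypes=gm, flipped_mask=flipped, duplicate_pairs=pairs)
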