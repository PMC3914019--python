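"""Desk-scale re-implementations of the three low-coverage caller classes.

* single-sample: per sample-site maximum-likelihood genotype under a flat
  prior, with a phred call-quality threshold;
* multi-sample: per-site allele frequency estimated by EM over genotype
  likelihoods, a phred likelihood-ratio site test, and posterior-mode
  genotypes under a Hardy-Weinberg prior;
* LD-aware: iterative haplotype resampling against a Li-Stephens diploid
  copying HMM over the other samples' current haplotypes (a MaCH/Thunder
  style refinement loop).

Genotype likelihoods use the standard per-read independent binomial model
with symmetric base error: with r reference and a alternate reads out of
n = r + a,

    L(D | hom-ref) = C(n,a) e^a (1-e)^r
    L(D | het)     = C(n,a) 0.5^n
    L(D | hom-alt) = C(n,a) (1-e)^a e^r

PL values follow VCF convention: round(-10 log10 L), normalized so the
minimum of each triple is 0, capped at 255.  Ties in genotype argmaxes
break toward the lower dosage (reference first), as real callers do.

No pedigree information enters any caller: none of these functions accepts
a pedigree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _hmm_kernels as _kernels
from ._utils import ParameterError, check, check_probability
from .simulate import MISSING, GenotypeMatrix, PileupMatrix

PL_CAP = 255
LOG10 = math.log(10.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class LikelihoodSet:
    """Per-sample per-site phred-scaled genotype likelihoods (PL triples).

    ``pl`` has shape (n_samples, n_sites, 3) ordered (hom-ref, het,
    hom-alt); each triple is min-normalized to 0 and capped at 255.
    """

    pl: np.ndarray
    sample_ids: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.pl = np.asarray(self.pl, dtype=np.int16)
        if self.pl.ndim != 3 or self.pl.shape[2] != 3:
            raise ParameterError("pl must have shape (n_samples, n_sites, 3)")
        if np.any(self.pl < 0) or np.any(self.pl > PL_CAP):
            raise ParameterError(f"PL entries must lie in [0, {PL_CAP}]")
        if np.any(self.pl.min(axis=2) != 0):
            raise ParameterError("each PL triple must have minimum 0")

    def linear(self) -> np.ndarray:
        """Linear-scale likelihoods normalized so the per-triple max is 1."""
        return np.power(10.0, -self.pl / 10.0)


@dataclass
class CallSet:
    """Genotype calls plus per-site variant flags and qualities."""

    genotypes: GenotypeMatrix
    site_variant_flag: np.ndarray
    call_quality: np.ndarray
    pl: LikelihoodSet | None = None
    depth: np.ndarray | None = None
    method: str = ""

    def __post_init__(self) -> None:
        self.site_variant_flag = np.asarray(self.site_variant_flag, dtype=bool)
        self.call_quality = np.asarray(self.call_quality, dtype=float)
        g = self.genotypes.genotypes
        expected = np.any((g > 0) & (g != MISSING), axis=0)
        if not np.array_equal(self.site_variant_flag, expected):
            raise ParameterError(
                "site_variant_flag must be true iff some non-missing genotype > 0"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.genotypes.sample_ids

    @property
    def positions(self) -> np.ndarray:
        return self.genotypes.positions


def _make_callset(
    genotypes: np.ndarray,
    pileups: PileupMatrix,
    call_quality: np.ndarray,
    pl: LikelihoodSet | None,
    method: str,
) -> CallSet:
    gm = GenotypeMatrix(
        genotypes=genotypes.astype(np.int8),
        sample_ids=list(pileups.sample_ids),
        positions=pileups.positions.copy(),
        ref_allele=pileups.ref_allele.copy(),
        alt_allele=pileups.alt_allele.copy(),
    )
    flag = np.any((genotypes > 0) & (genotypes != MISSING), axis=0)
    return CallSet(gm, flag, call_quality, pl=pl, depth=pileups.depth.copy(), method=method)


# ---------------------------------------------------------------------------
# genotype likelihoods
# ---------------------------------------------------------------------------


def genotype_likelihoods(
    ref_count: int, alt_count: int, base_error: float
) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood triple and PL triple for one sample-site.

    Returns ``(L, PL)`` with genotype order (hom-ref, het, hom-alt).
    """
    check(ref_count >= 0 and alt_count >= 0, "read counts must be non-negative")
    check(0.0 <= base_error < 0.5, "base_error must be in [0, 0.5)")
    r, a, e = ref_count, alt_count, base_error
    n = r + a
    comb = math.comb(n, a)
    lik = np.array(
        [
            comb * e**a * (1.0 - e) ** r,
            comb * 0.5**n,
            comb * (1.0 - e) ** a * e**r,
        ]
    )
    with np.errstate(divide="ignore"):
        pl = -10.0 * np.log10(lik)
    pl = np.where(np.isfinite(pl), np.round(pl), PL_CAP)
    pl = pl - pl.min()
    pl = np.minimum(pl, PL_CAP).astype(np.int16)
    return lik, pl


def _log_likelihood_matrix(pileups: PileupMatrix, base_error: float) -> np.ndarray:
    """Natural-log likelihoods, shape (n_samples, n_sites, 3), no binomial
    coefficient (it cancels in every normalized quantity)."""
    check(0.0 <= base_error < 0.5, "base_error must be in [0, 0.5)")
    r = pileups.ref_count.astype(float)
    a = pileups.alt_count.astype(float)
    n = r + a
    e = base_error
    with np.errstate(divide="ignore", invalid="ignore"):
        log_e = math.log(e) if e > 0 else -np.inf
        log_1e = math.log1p(-e)
        ll = np.stack(
            [
                np.where(a > 0, a * log_e, 0.0) + r * log_1e,
                n * math.log(0.5),
                a * log_1e + np.where(r > 0, r * log_e, 0.0),
            ],
            axis=-1,
        )
    return ll


def likelihoods_from_pileups(pileups: PileupMatrix, base_error: float) -> LikelihoodSet:
    """PL-encoded genotype likelihoods for every sample-site."""
    ll = _log_likelihood_matrix(pileups, base_error)
    pl = -10.0 / LOG10 * (ll - ll.max(axis=2, keepdims=True))
    pl = np.where(np.isfinite(pl), np.round(pl), PL_CAP)
    pl = np.minimum(pl, PL_CAP).astype(np.int16)
    return LikelihoodSet(pl, list(pileups.sample_ids), pileups.positions.copy())


# ---------------------------------------------------------------------------
# single-sample calling
# ---------------------------------------------------------------------------


def call_single_sample(
    pileups: PileupMatrix,
    base_error: float = 0.005,
    min_call_quality: float = 4.0,
) -> CallSet:
    """Per sample-site maximum-likelihood genotype under a flat prior.

    Call quality is the phred difference between the best and second-best
    genotype likelihood; calls below ``min_call_quality`` or with zero
    depth are missing.  Each sample is processed independently.
    """
    ll = _log_likelihood_matrix(pileups, base_error)
    # argmax over (hom-ref, het, hom-alt); np.argmax takes the first of a
    # tie, i.e. the lower dosage
    g = np.argmax(ll, axis=2).astype(np.int8)
    part = np.partition(ll, 2, axis=2)
    qual = 10.0 / LOG10 * (part[..., 2] - part[..., 1])
    depth = pileups.depth
    g = np.where((depth == 0) | (qual < min_call_quality), MISSING, g).astype(np.int8)

    alt_called = (g > 0) & (g != MISSING)
    site_qual = np.where(alt_called, qual, 0.0).max(axis=0)
    pl = likelihoods_from_pileups(pileups, base_error)
    return _make_callset(g, pileups, site_qual, pl, "single")


# ---------------------------------------------------------------------------
# multi-sample calling
# ---------------------------------------------------------------------------


def _hwe_priors(q: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype priors for frequency array q, shape (..., 3)."""
    q = np.asarray(q, dtype=float)
    return np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=-1)


def estimate_frequency_em(
    site_likelihoods: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
    init: float = 0.25,
    return_history: bool = False,
):
    """Maximum-likelihood alternate-allele frequency for one site by EM.

    ``site_likelihoods`` is an (n_samples, 3) array of linear-scale
    genotype likelihoods.  The E-step computes genotype posteriors under
    HWE(q); the M-step sets q to half the mean expected dosage.  Stops when
    |dq| < ``tol``.  If every sample's likelihood triple is flat (no data)
    the initialization is returned unchanged.
    """
    lik = np.asarray(site_likelihoods, dtype=float)
    check(lik.ndim == 2 and lik.shape[1] == 3, "site_likelihoods must be (n, 3)")
    check(lik.shape[0] >= 1, "need at least one sample")
    flat = np.all(lik == lik[:, :1], axis=1)
    if np.all(flat):
        return (init, [init]) if return_history else init
    q = float(init)
    history = [q]
    dosage = np.array([0.0, 1.0, 2.0])
    for _ in range(max_iter):
        post = _hwe_priors(q) * lik
        post /= post.sum(axis=1, keepdims=True)
        q_new = float((post @ dosage).mean() / 2.0)
        history.append(q_new)
        if abs(q_new - q) < tol:
            q = q_new
            break
        q = q_new
    return (q, history) if return_history else q


def _em_frequencies(
    lik: np.ndarray, tol: float = 1e-8, max_iter: int = 200, init: float = 0.25
) -> np.ndarray:
    """Vectorized per-site EM over a (n_samples, n_sites, 3) likelihood array."""
    n, s, _ = lik.shape
    q = np.full(s, init)
    dosage = np.array([0.0, 1.0, 2.0])
    active = np.ones(s, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        prior = _hwe_priors(q[idx])  # (k, 3)
        post = prior[None, :, :] * lik[:, idx, :]
        post /= post.sum(axis=2, keepdims=True)
        q_new = (post @ dosage).mean(axis=0) / 2.0
        moved = np.abs(q_new - q[idx]) >= tol
        q[idx] = q_new
        active[idx] = moved
    # flat sites keep the initialization (documented degenerate case)
    flat = np.all(lik == lik[:, :, :1], axis=(0, 2))
    q[flat] = init
    return q


def _site_loglik(lik: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Observed-data log10-likelihood per site, summed over samples."""
    prior = _hwe_priors(q)  # (s, 3)
    mix = (prior[None, :, :] * lik).sum(axis=2)
    with np.errstate(divide="ignore"):
        return np.log10(mix).sum(axis=0)


def call_multi_sample(
    pileups: PileupMatrix,
    base_error: float = 0.005,
    min_site_quality: float = 4.0,
) -> CallSet:
    """Cohort-frequency-prior calling.

    Per site: q is estimated by EM over all samples' genotype likelihoods;
    the site is flagged variant iff the phred-scaled likelihood ratio of
    q-hat against q = 0 reaches ``min_site_quality``; genotypes are the
    posterior mode under the HWE(q-hat) prior.  At flagged sites zero-depth
    samples receive the prior-mode genotype (their likelihood is flat, so
    the posterior is the prior); at unflagged sites every genotype is
    hom-ref.  A flagged site whose posterior modes are all hom-ref gets its
    best-supported carrier promoted to that sample's most likely alternate
    genotype, so the variant flag always has a carrier behind it.
    """
    check(pileups.n_samples >= 2, "multi-sample calling needs >= 2 samples")
    ll = _log_likelihood_matrix(pileups, base_error)
    lik = np.exp(ll - ll.max(axis=2, keepdims=True))
    q = _em_frequencies(lik)
    lrt_phred = 10.0 * (_site_loglik(lik, q) - _site_loglik(lik, np.zeros_like(q)))
    flagged = lrt_phred >= min_site_quality

    post = _hwe_priors(q)[None, :, :] * lik
    g = np.argmax(post, axis=2).astype(np.int8)  # ties break toward lower dosage
    g[:, ~flagged] = 0
    # a flagged site must carry the alternate allele somewhere: when every
    # posterior mode is hom-ref (weak-evidence flags), promote the sample
    # with the strongest non-reference support to its best alt genotype
    post_norm = post / post.sum(axis=2, keepdims=True)
    p_alt = post_norm[:, :, 1] + post_norm[:, :, 2]
    needs_carrier = flagged & ~np.any(g > 0, axis=0)
    for s_idx in np.flatnonzero(needs_carrier):
        i = int(np.argmax(p_alt[:, s_idx]))
        g[i, s_idx] = 1 + int(post_norm[i, s_idx, 2] > post_norm[i, s_idx, 1])
    return _make_callset(
        g, pileups, np.maximum(lrt_phred, 0.0), likelihoods_from_pileups(pileups, base_error), "multi"
    )


# ---------------------------------------------------------------------------
# Li-Stephens diploid copying HMM
# ---------------------------------------------------------------------------


def _genotype_given_templates(template_error: float) -> np.ndarray:
    """m[u, v, g] = P(genotype g | copied template alleles u, v).

    Each copied allele is flipped independently with ``template_error``.
    """
    e = template_error
    p = np.array([e, 1.0 - e])  # P(allele = 1 | template allele u)
    m = np.empty((2, 2, 3))
    for u in (0, 1):
        for v in (0, 1):
            p1, p2 = p[u], p[v]
            m[u, v] = [
                (1 - p1) * (1 - p2),
                p1 * (1 - p2) + (1 - p1) * p2,
                p1 * p2,
            ]
    return m


class DiploidCopyingHMM:
    """Exact forward-backward over ordered template pairs.

    Hidden state at each site is an ordered pair of template haplotypes;
    each of the two copied haplotypes independently switches to a uniformly
    chosen template with probability ``recomb_switch`` per adjacent-site
    interval.  Emission at a site sums over the latent genotype:
    sum_g P(g | template alleles, template_error) * L(D | g).

    The factorized transition keeps every update O(H^2) for H templates.
    """

    def __init__(
        self,
        sample_likelihoods: np.ndarray,
        templates: np.ndarray,
        recomb_switch: float = 0.01,
        template_error: float = 0.01,
    ) -> None:
        lik = np.asarray(sample_likelihoods, dtype=float)
        templates = np.asarray(templates, dtype=np.int8)
        check(templates.ndim == 2 and templates.shape[0] >= 1, "empty template set")
        check(templates.shape[0] >= 2, "need >= 2 templates")
        check(lik.ndim == 2 and lik.shape[1] == 3, "likelihoods must be (n_sites, 3)")
        if lik.shape[0] != templates.shape[1]:
            raise ParameterError("likelihood count must match template site count")
        check_probability(recomb_switch, "recomb_switch")
        check_probability(template_error, "template_error")

        self.lik = lik
        self.templates = templates
        self.H = templates.shape[0]
        self.S = templates.shape[1]
        self.r = recomb_switch
        self.e = template_error
        self.m = _genotype_given_templates(template_error)  # (2,2,3)
        # per-site 2x2 emission weights W[s, u, v] = sum_g m[u,v,g] L[s,g]
        self.W = np.einsum("uvg,sg->suv", self.m, lik)
        a = templates
        self.E = self.W[np.arange(self.S)[None, None, :], a[:, None, :], a[None, :, :]]
        # E has shape (H, H, S); E[j, k, s] is the emission for state (j, k)
        self.templates_i64 = templates.astype(np.int64)
        self._alphas: np.ndarray | None = None

    def _forward(self) -> np.ndarray:
        c = 1.0 - self.r
        d = self.r / self.H
        self._alphas = _kernels.forward(self.E, c, d)
        return self._alphas

    def posteriors(self) -> np.ndarray:
        """Per-site genotype posterior triples (rows sum to 1)."""
        alphas = self._alphas if self._alphas is not None else self._forward()
        c = 1.0 - self.r
        d = self.r / self.H
        betas = _kernels.backward(self.E, c, d)
        return _kernels.genotype_posteriors(
            alphas, betas, self.templates_i64, self.m, self.lik, c, d
        )

    def sample_haplotype_pair(self, rng: np.random.Generator) -> np.ndarray:
        """Draw one haplotype pair from the posterior path distribution.

        Backward-samples a state path from the forward lattice, then draws
        the allele pair at each site given the state and the genotype
        likelihoods.  Returns an (2, n_sites) allele array.
        """
        alphas = self._alphas if self._alphas is not None else self._forward()
        S = self.S
        c = 1.0 - self.r
        d = self.r / self.H
        path = _kernels.sample_path(alphas, c, d, rng.random(S))

        sites = np.arange(S)
        p_alt = np.array([self.e, 1.0 - self.e])
        p1 = p_alt[self.templates[path[:, 0], sites]]
        p2 = p_alt[self.templates[path[:, 1], sites]]
        probs = np.stack(
            [
                (1 - p1) * (1 - p2) * self.lik[:, 0],
                (1 - p1) * p2 * self.lik[:, 1],
                p1 * (1 - p2) * self.lik[:, 1],
                p1 * p2 * self.lik[:, 2],
            ],
            axis=1,
        )
        cdf = np.cumsum(probs, axis=1)
        u = rng.random(S) * cdf[:, -1]
        combo = (cdf < u[:, None]).sum(axis=1)
        haps = np.empty((2, S), dtype=np.int8)
        haps[0] = combo >> 1
        haps[1] = combo & 1
        return haps


def hmm_posteriors(
    sample_likelihoods: np.ndarray,
    templates: np.ndarray,
    recomb_switch: float = 0.01,
    template_error: float = 0.01,
) -> np.ndarray:
    """Exact per-site genotype posteriors under the diploid copying model."""
    hmm = DiploidCopyingHMM(sample_likelihoods, templates, recomb_switch, template_error)
    return hmm.posteriors()


# ---------------------------------------------------------------------------
# LD-aware calling
# ---------------------------------------------------------------------------


def call_ld_aware(
    pileups: PileupMatrix,
    base_error: float = 0.005,
    n_rounds: int = 20,
    n_templates: int = 40,
    recomb_switch: float = 0.01,
    template_error: float = 0.01,
    min_site_quality: float = 4.0,
    seed: int = 0,
) -> CallSet:
    """Iterative haplotype-resampling genotype refinement.

    As in production LD-aware pipelines, refinement operates on a candidate
    variant-site list discovered by a multi-sample pre-pass (the EM
    likelihood-ratio site test at ``min_site_quality``); every other site
    is a reference call for all samples.  At candidate sites haplotypes are
    initialized from single-sample MAP genotypes with random phase, then
    each round updates every sample in random order: the sample's haplotype
    pair is resampled from the posterior path of the copying HMM run
    against up to ``n_templates`` haplotypes drawn from the other samples'
    current estimates.  Final genotypes are the per-site posterior mode
    averaged over the final half of the rounds.
    """
    check(n_rounds >= 1, "n_rounds must be >= 1")
    check(pileups.n_samples >= 3, "LD-aware calling needs >= 3 samples")
    check(n_templates >= 2, "n_templates must be >= 2")
    rng = np.random.default_rng(seed)

    n, s_all = pileups.n_samples, pileups.n_sites
    ll_all = _log_likelihood_matrix(pileups, base_error)
    lik_all = np.exp(ll_all - ll_all.max(axis=2, keepdims=True))

    # candidate variant sites from the multi-sample likelihood-ratio test
    q = _em_frequencies(lik_all)
    lrt = 10.0 * (_site_loglik(lik_all, q) - _site_loglik(lik_all, np.zeros_like(q)))
    candidate = lrt >= min_site_quality
    cand_idx = np.flatnonzero(candidate)
    if cand_idx.size == 0:
        g_full = np.zeros((n, s_all), dtype=np.int8)
        return _make_callset(
            g_full,
            pileups,
            np.zeros(s_all),
            likelihoods_from_pileups(pileups, base_error),
            "ld",
        )

    s = cand_idx.size
    ll = ll_all[:, cand_idx, :]
    lik = lik_all[:, cand_idx, :]

    g0 = np.argmax(ll, axis=2)
    haps = np.zeros((2 * n, s), dtype=np.int8)
    haps[0::2] = (g0 >= 1).astype(np.int8)
    haps[1::2] = (g0 == 2).astype(np.int8)
    flip = (g0 == 1) & (rng.random((n, s)) < 0.5)  # random phase at het sites
    haps[0::2][flip] = 0
    haps[1::2][flip] = 1

    burn_in = n_rounds // 2
    post_acc = np.zeros((n, s, 3))
    n_acc = 0
    all_rows = np.arange(2 * n)
    for rnd in range(n_rounds):
        keep_posteriors = rnd >= burn_in
        for i in rng.permutation(n):
            others = np.delete(all_rows, [2 * i, 2 * i + 1])
            if others.size > n_templates:
                others = rng.choice(others, size=n_templates, replace=False)
            hmm = DiploidCopyingHMM(lik[i], haps[others], recomb_switch, template_error)
            hmm._forward()
            if keep_posteriors:
                post_acc[i] += hmm.posteriors()
            haps[2 * i : 2 * i + 2] = hmm.sample_haplotype_pair(rng)
        if keep_posteriors:
            n_acc += 1

    post = post_acc / n_acc
    g = np.argmax(post, axis=2).astype(np.int8)  # first-of-tie = lower dosage

    with np.errstate(divide="ignore"):
        p_ref = np.clip(post[:, :, 0], 1e-12, 1.0)
        site_qual = np.minimum(-10.0 * np.log10(p_ref).sum(axis=0), 9999.0)
    g_full = np.zeros((n, s_all), dtype=np.int8)
    g_full[:, cand_idx] = g
    qual_full = np.zeros(s_all)
    qual_full[cand_idx] = site_qual
    return _make_callset(
        g_full, pileups, qual_full, likelihoods_from_pileups(pileups, base_error), "ld"
    )
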