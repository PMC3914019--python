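"""Kinship coefficients and kinship-corrected allele frequencies.

Pedigree kinship uses the standard recursion in generation order; empirical
kinship is the centered-dosage moment estimator; allele frequencies are
corrected for relatedness with the best linear unbiased estimate (BLUE),
which weights samples by the inverse kinship matrix:

    q_BLUE = (1' Phi^-1 x) / (1' Phi^-1 1),   x_i = g_i / 2.

With everyone unrelated and non-inbred (Phi = I/2) this reduces exactly to
the naive allele prevalence; in pedigree cohorts it down-weights large
sibships, removing the upward bias from alleles identical by descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import DimensionError, EmptyInputError, check
from .simulate import MISSING, GenotypeMatrix, PedigreeTable


@dataclass
class KinshipMatrix:
    """Symmetric pairwise kinship; diagonal holds self-kinship 0.5(1+F)."""

    coefficients: np.ndarray
    sample_ids: list[str]
    source: str  # "pedigree" or "empirical"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        n = len(self.sample_ids)
        if self.coefficients.shape != (n, n):
            raise DimensionError("kinship matrix shape mismatch")

    def submatrix(self, sample_ids: list[str]) -> "KinshipMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return KinshipMatrix(
            self.coefficients[np.ix_(idx, idx)].copy(), list(sample_ids), self.source
        )

    def to_long_frame(self) -> pd.DataFrame:
        n = len(self.sample_ids)
        iu = np.triu_indices(n)
        return pd.DataFrame(
            {
                "id1": [self.sample_ids[i] for i in iu[0]],
                "id2": [self.sample_ids[j] for j in iu[1]],
                "kinship": self.coefficients[iu],
            }
        )


def pedigree_kinship(pedigree: PedigreeTable) -> KinshipMatrix:
    """Kinship coefficients from the pedigree by the standard recursion.

    Founders are unrelated and non-inbred (phi_ii = 1/2, phi_ij = 0); for a
    non-founder i with parents f and m, phi(i, j) = [phi(f, j) + phi(m, j)]/2
    for previously processed j != i, and phi(i, i) = [1 + phi(f, m)]/2.
    Results are exact dyadic rationals represented in floating point.
    """
    n = pedigree.n
    phi = np.zeros((n, n))
    for i, iid in enumerate(pedigree.individual_id):
        fa, mo = pedigree.father_id[i], pedigree.mother_id[i]
        if fa is None:
            phi[i, i] = 0.5
        else:
            pf, pm = pedigree.index_of(fa), pedigree.index_of(mo)
            phi[i, :i] = 0.5 * (phi[pf, :i] + phi[pm, :i])
            phi[:i, i] = phi[i, :i]
            phi[i, i] = 0.5 * (1.0 + phi[pf, pm])
    return KinshipMatrix(phi, list(pedigree.individual_id), "pedigree")


def empirical_kinship(
    genotypes: GenotypeMatrix,
    freqs: np.ndarray | None = None,
    maf_floor: float = 0.01,
) -> KinshipMatrix:
    """Centered-dosage moment estimator of pairwise kinship.

    phi_ij = mean over retained sites of
    (g_i - 2q)(g_j - 2q) / (2 q (1-q)) / 2, with sites missing in either
    sample skipped pairwise and sites with minor-allele frequency below
    ``maf_floor`` excluded (they destabilize the denominator).
    """
    check(genotypes.n_samples >= 2, "need >= 2 samples", EmptyInputError)
    g = genotypes.genotypes.astype(float)
    if freqs is None:
        freqs = genotypes.allele_frequencies()
    freqs = np.asarray(freqs, dtype=float)
    maf = np.minimum(freqs, 1.0 - freqs)
    keep = np.isfinite(maf) & (maf >= maf_floor)
    if not np.any(keep):
        raise EmptyInputError("no site with frequency inside the MAF floor")
    g = g[:, keep]
    q = freqs[keep]

    obs = g != MISSING
    z = np.where(obs, (g - 2.0 * q) / np.sqrt(2.0 * q * (1.0 - q)), 0.0)
    pair_counts = obs.astype(float) @ obs.T.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = 0.5 * (z @ z.T) / pair_counts
    return KinshipMatrix(phi, list(genotypes.sample_ids), "empirical")


def kinship_histograms(
    empirical: KinshipMatrix,
    pedigree: KinshipMatrix,
    pedigree_values: list[float] | None = None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Distribution of empirical kinship within groups of equal pedigree
    kinship (one histogram row-set per pedigree value).

    Groups sample pairs (i < j) by their exact pedigree kinship; empty
    groups yield zero-count histograms.  Returns a long-format table with
    columns (pedigree_value, bin_low, bin_high, count) plus per-group
    summary columns n_pairs and mean_empirical.
    """
    if empirical.sample_ids != pedigree.sample_ids:
        raise DimensionError("kinship matrices cover different samples")
    n = len(empirical.sample_ids)
    iu = np.triu_indices(n, k=1)
    ped_vals = pedigree.coefficients[iu]
    emp_vals = empirical.coefficients[iu]
    if pedigree_values is None:
        pedigree_values = sorted(set(np.round(ped_vals, 12)))
    if grid is None:
        grid = np.linspace(-0.1, 0.6, 71)
    rows = []
    for v in pedigree_values:
        mask = np.isclose(ped_vals, v, rtol=0.0, atol=1e-12)
        vals = emp_vals[mask & np.isfinite(emp_vals)]
        counts, edges = np.histogram(vals, bins=grid)
        mean = vals.mean() if vals.size else np.nan
        for c, lo, hi in zip(counts, edges[:-1], edges[1:]):
            rows.append((v, lo, hi, int(c), int(vals.size), mean))
    return pd.DataFrame(
        rows,
        columns=["pedigree_value", "bin_low", "bin_high", "count", "n_pairs", "mean_empirical"],
    )


def unrelated_subset(kinship: KinshipMatrix, threshold: float = 0.1) -> list[str]:
    """Greedy maximal subset with all pairwise kinship below ``threshold``.

    Candidates are considered in order of ascending total kinship (ties by
    index), so the least-connected samples enter first; deterministic.
    """
    check(threshold > 0, "threshold must be positive")
    phi = kinship.coefficients
    n = len(kinship.sample_ids)
    off = phi - np.diag(np.diag(phi))
    order = np.lexsort((np.arange(n), off.sum(axis=1)))
    chosen: list[int] = []
    for i in order:
        if all(phi[i, j] < threshold for j in chosen):
            chosen.append(int(i))
    chosen.sort()
    return [kinship.sample_ids[i] for i in chosen]


@dataclass
class FrequencyEstimate:
    """Naive and BLUE per-site allele-frequency estimates."""

    positions: np.ndarray
    naive: np.ndarray
    blue: np.ndarray
    n_clipped: int = 0
    failed_sites: list[int] = field(default_factory=list)

    @property
    def correction(self) -> np.ndarray:
        return self.blue - self.naive

    @property
    def rms_correction(self) -> float:
        c = self.correction
        c = c[np.isfinite(c)]
        return float(np.sqrt(np.mean(c**2))) if c.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "naive": self.naive,
                "blue": self.blue,
                "correction": self.correction,
            }
        )


def blue_frequencies(
    genotypes: GenotypeMatrix, kinship: KinshipMatrix
) -> FrequencyEstimate:
    """Kinship-corrected (BLUE) allele frequencies per site.

    Per site, over the non-missing samples with kinship submatrix Phi and
    half-dosages x: BLUE = (1' Phi^-1 x)/(1' Phi^-1 1); naive = mean(x).
    Weight vectors are cached per missingness pattern.  Singular
    submatrices are recorded and the site reported as NaN; estimates are
    clipped to [0, 1] with the clip count logged.
    """
    if genotypes.sample_ids != kinship.sample_ids:
        raise DimensionError("genotypes and kinship cover different samples")
    g = genotypes.genotypes
    phi = kinship.coefficients
    n_sites = genotypes.n_sites
    naive = np.full(n_sites, np.nan)
    blue = np.full(n_sites, np.nan)
    failed: list[int] = []
    weights_cache: dict[bytes, np.ndarray | None] = {}
    n_clipped = 0
    for s in range(n_sites):
        obs = g[:, s] != MISSING
        if not np.any(obs):
            failed.append(s)
            continue
        x = g[obs, s] / 2.0
        naive[s] = x.mean()
        key = obs.tobytes()
        if key not in weights_cache:
            sub = phi[np.ix_(obs, obs)]
            try:
                w = np.linalg.solve(sub, np.ones(sub.shape[0]))
                denom = w.sum()
                if not np.isfinite(denom) or abs(denom) < 1e-12:
                    raise np.linalg.LinAlgError("degenerate weight sum")
                weights_cache[key] = w / denom
            except np.linalg.LinAlgError:
                weights_cache[key] = None
        w = weights_cache[key]
        if w is None:
            failed.append(s)
            continue
        est = float(w @ x)
        if est < 0.0 or est > 1.0:
            n_clipped += 1
            est = min(max(est, 0.0), 1.0)
        blue[s] = est
    return FrequencyEstimate(
        positions=genotypes.positions.copy(),
        naive=naive,
        blue=blue,
        n_clipped=n_clipped,
        failed_sites=failed,
    )
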