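"""Call-set evaluation against chip genotypes.

Implements the comparison statistics used to judge low-coverage callers
against a fixed-content genotyping array:

* marker QC — duplicate-pair discordance, an exact Hardy-Weinberg test on
  an unrelated subset, and the allele-flip filter (per-marker concordance
  below 2%);
* per-sample concordance C_S = N_{S,m} / N_{S,v} over chip genotypes with
  at least one non-reference allele, with missing calls interpreted as
  homozygous reference;
* per-sample false-positive rate: the fraction of a sample's non-reference
  calls that are homozygous reference on the chip;
* frequency-binned site finding (a site is "found" if any sample is called
  with an alternate allele there, regardless of genotype agreement), and
  the single-sample discovery model P(found) = 1 - (1-p)^f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._utils import DimensionError, EmptyInputError, ParameterError, check
from .callers import CallSet
from .simulate import MISSING, ChipDataset

DEPTH_STRATA = ((0.0, 5.0), (5.0, 10.0), (10.0, np.inf))  # <5x, 5-10x, >10x


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact conditional Hardy-Weinberg test (two-sided, by probability).

    Enumerates every heterozygote count compatible with the observed allele
    counts, computes each configuration's conditional probability exactly
    (rational arithmetic), and returns the total probability of
    configurations no more likely than the observed one.  Monomorphic input
    returns p = 1.
    """
    check(min(n_homref, n_het, n_homalt) >= 0, "genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n < 1:
        raise ParameterError("need at least one genotyped sample")
    n_alt = 2 * n_homalt + n_het
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0

    def prob(h: int) -> Fraction:
        # P(h hets | n samples, n_rare rare alleles), conditional on margins
        hom_rare = (n_rare - h) // 2
        hom_common = n - h - hom_rare
        num = Fraction(
            2**h * math.factorial(n),
            math.factorial(hom_rare) * math.factorial(h) * math.factorial(hom_common),
        )
        return num / math.comb(2 * n, n_rare)

    h_obs = n_het
    hets = range(n_rare % 2, n_rare + 1, 2)
    p_obs = prob(h_obs)
    p_val = sum((p for h in hets if (p := prob(h)) <= p_obs), Fraction(0))
    return float(min(p_val, Fraction(1)))


# ---------------------------------------------------------------------------
# marker alignment helpers
# ---------------------------------------------------------------------------


def _align_markers(calls: CallSet, chip: ChipDataset) -> np.ndarray:
    """Column index into the call set for each chip marker (-1 if absent)."""
    call_pos = calls.positions
    chip_pos = chip.genotypes.positions
    idx = np.searchsorted(call_pos, chip_pos)
    idx = np.clip(idx, 0, len(call_pos) - 1)
    ok = call_pos[idx] == chip_pos
    out = np.where(ok, idx, -1)
    if not np.any(ok):
        raise EmptyInputError("no overlapping markers between calls and chip")
    return out


def _shared_samples(calls: CallSet, chip: ChipDataset) -> list[str]:
    chip_ids = set(chip.genotypes.sample_ids)
    return [s for s in calls.sample_ids if s in chip_ids]


def _called_dosage(calls: CallSet) -> np.ndarray:
    """Call genotypes with missing interpreted as homozygous reference."""
    g = calls.genotypes.genotypes.copy()
    g[g == MISSING] = 0
    return g


# ---------------------------------------------------------------------------
# marker QC
# ---------------------------------------------------------------------------


@dataclass
class MarkerQCReport:
    """Per-marker QC outcome; indices refer to chip marker columns."""

    positions: np.ndarray
    per_marker_concordance: np.ndarray
    dup_discordant_removed: np.ndarray
    hwe_removed: np.ndarray
    flipped_removed: np.ndarray
    monomorphic_mask: np.ndarray
    surviving_mask: np.ndarray
    call_column: np.ndarray
    shared_samples: list[str] = field(default_factory=list)
    removal_reason: dict[int, str] = field(default_factory=dict)

    @property
    def surviving_markers(self) -> np.ndarray:
        return np.flatnonzero(self.surviving_mask)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.positions)
        reason = np.array([self.removal_reason.get(i, "") for i in range(n)])
        return pd.DataFrame(
            {
                "position": self.positions,
                "concordance": self.per_marker_concordance,
                "monomorphic": self.monomorphic_mask,
                "surviving": self.surviving_mask,
                "removal_reason": reason,
            }
        )


def filter_markers(
    chip: ChipDataset,
    calls: CallSet,
    hwe_threshold: float = 1e-10,
    flip_threshold: float = 0.02,
    dup_max_discordant: int = 3,
    unrelated_samples: list[str] | None = None,
    flip_min_carriers: int = 5,
) -> MarkerQCReport:
    """Marker QC, applied in order: duplicates, HWE, flip concordance.

    * duplicate filter: markers with discordant genotypes in more than
      ``dup_max_discordant`` duplicate pairs are removed;
    * HWE filter: markers with exact-test p below ``hwe_threshold`` on the
      configured unrelated subset (default: all non-duplicate samples) are
      removed;
    * flip filter: markers whose concordance across all samples — computed
      like C_S but per marker, over samples with at least one chip
      alternate allele there — falls below ``flip_threshold`` are removed.
      The filter only fires when at least ``flip_min_carriers`` samples
      carry a chip alternate allele at the marker: a reversed marker shows
      near-zero concordance across many samples, whereas a rare variant
      missed by the caller would otherwise be removed on the evidence of a
      single carrier.

    Monomorphic markers are marked (excluded from concordance, retained
    for the false-positive rate).
    """
    call_col = _align_markers(calls, chip)
    shared = _shared_samples(calls, chip)
    if not shared:
        raise EmptyInputError("no shared samples between calls and chip")
    n_markers = chip.genotypes.n_sites
    chip_rows = {s: i for i, s in enumerate(chip.genotypes.sample_ids)}
    call_rows = {s: i for i, s in enumerate(calls.sample_ids)}

    removed = np.zeros(n_markers, dtype=bool)
    reason: dict[int, str] = {}

    # 1. duplicate-pair discordance
    dup_removed: list[int] = []
    if chip.duplicate_pairs:
        g = chip.genotypes.genotypes
        discordant = np.zeros(n_markers, dtype=np.int64)
        for a, b in chip.duplicate_pairs:
            ga, gb = g[chip_rows[a]], g[chip_rows[b]]
            both = (ga != MISSING) & (gb != MISSING)
            discordant += (both & (ga != gb)).astype(np.int64)
        dup_removed = np.flatnonzero(discordant > dup_max_discordant).tolist()
        for i in dup_removed:
            removed[i] = True
            reason[i] = "duplicate_discordance"

    # 2. Hardy-Weinberg on the unrelated subset
    if unrelated_samples is None:
        dup_ids = {b for _, b in chip.duplicate_pairs}
        unrelated_samples = [s for s in chip.genotypes.sample_ids if s not in dup_ids]
    rows = [chip_rows[s] for s in unrelated_samples]
    g_u = chip.genotypes.genotypes[rows]
    hwe_removed: list[int] = []
    for j in range(n_markers):
        if removed[j]:
            continue
        col = g_u[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        counts = np.bincount(col, minlength=3)
        if hwe_exact_test(int(counts[0]), int(counts[1]), int(counts[2])) < hwe_threshold:
            hwe_removed.append(j)
            removed[j] = True
            reason[j] = "hwe"

    # 3. flip filter: per-marker concordance across all samples
    chip_g = chip.genotypes.genotypes[[chip_rows[s] for s in shared]]
    called = _called_dosage(calls)[np.ix_([call_rows[s] for s in shared], call_col)]
    has_alt = (chip_g == 1) | (chip_g == 2)
    match = has_alt & (called == chip_g)
    denom = has_alt.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        concordance = np.where(denom > 0, match.sum(axis=0) / denom, np.nan)
    flip_removed: list[int] = []
    for j in range(n_markers):
        if removed[j] or np.isnan(concordance[j]) or denom[j] < flip_min_carriers:
            continue
        if concordance[j] < flip_threshold:
            flip_removed.append(j)
            removed[j] = True
            reason[j] = "flip_concordance"

    return MarkerQCReport(
        positions=chip.genotypes.positions.copy(),
        per_marker_concordance=concordance,
        dup_discordant_removed=np.array(dup_removed, dtype=np.int64),
        hwe_removed=np.array(hwe_removed, dtype=np.int64),
        flipped_removed=np.array(flip_removed, dtype=np.int64),
        monomorphic_mask=chip.monomorphic_mask.copy(),
        surviving_mask=~removed,
        call_column=call_col,
        shared_samples=shared,
        removal_reason=reason,
    )


# ---------------------------------------------------------------------------
# per-sample concordance and false-positive rate
# ---------------------------------------------------------------------------


def false_positive_rate(
    calls: CallSet, chip: ChipDataset, qc: MarkerQCReport
) -> pd.DataFrame:
    """Per-sample false-positive rate, in both marker conventions.

    ``fpr`` includes chip-monomorphic surviving markers in the denominator;
    ``fpr_polymorphic`` restricts to chip-polymorphic markers.  Samples
    whose caller makes no non-reference call have NaN (undefined), not 0.
    """
    shared = qc.shared_samples
    chip_rows = {s: i for i, s in enumerate(chip.genotypes.sample_ids)}
    call_rows = {s: i for i, s in enumerate(calls.sample_ids)}
    use = qc.surviving_mask & (qc.call_column >= 0)
    cols = np.flatnonzero(use)
    chip_g = chip.genotypes.genotypes[np.ix_([chip_rows[s] for s in shared], cols)]
    called = _called_dosage(calls)[np.ix_([call_rows[s] for s in shared], qc.call_column[cols])]

    records = []
    poly = ~qc.monomorphic_mask[cols]
    for i, s in enumerate(shared):
        cg, og = chip_g[i], called[i]
        ok = cg != MISSING
        for label, mask in (("fpr", ok), ("fpr_polymorphic", ok & poly)):
            den = mask & (og > 0)
            num = den & (cg == 0)
            records.append((s, label, num.sum(), den.sum()))
    df = pd.DataFrame(records, columns=["sample_id", "convention", "n_false", "n_called_alt"])
    wide = {}
    for label in ("fpr", "fpr_polymorphic"):
        sub = df[df.convention == label].set_index("sample_id")
        with np.errstate(invalid="ignore", divide="ignore"):
            wide[label] = sub.n_false / sub.n_called_alt.where(sub.n_called_alt > 0)
    out = pd.DataFrame(wide)
    out.index.name = "sample_id"
    return out.reset_index()


def sample_concordance(
    calls: CallSet, chip: ChipDataset, qc: MarkerQCReport
) -> pd.DataFrame:
    """Per-sample concordance report.

    For each shared sample S, over surviving non-monomorphic markers:
    N_{S,v} counts chip genotypes with at least one alternate allele
    (chip-missing excluded); N_{S,m} counts those the caller matches
    exactly, with missing calls read as hom-ref.  C_S = N_{S,m}/N_{S,v},
    NaN when N_{S,v} = 0.  Mean depth and both FPR conventions are
    attached.
    """
    shared = qc.shared_samples
    chip_rows = {s: i for i, s in enumerate(chip.genotypes.sample_ids)}
    call_rows = {s: i for i, s in enumerate(calls.sample_ids)}
    use = qc.surviving_mask & ~qc.monomorphic_mask & (qc.call_column >= 0)
    cols = np.flatnonzero(use)
    chip_g = chip.genotypes.genotypes[np.ix_([chip_rows[s] for s in shared], cols)]
    called = _called_dosage(calls)[np.ix_([call_rows[s] for s in shared], qc.call_column[cols])]

    has_alt = (chip_g == 1) | (chip_g == 2)
    match = has_alt & (called == chip_g)
    n_v = has_alt.sum(axis=1)
    n_m = match.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_s = np.where(n_v > 0, n_m / np.maximum(n_v, 1), np.nan)

    if calls.depth is not None:
        depth_by_sample = dict(zip(calls.sample_ids, calls.depth.mean(axis=1)))
        mean_depth = np.array([depth_by_sample[s] for s in shared])
    else:
        mean_depth = np.full(len(shared), np.nan)

    df = pd.DataFrame(
        {
            "sample_id": shared,
            "n_variant": n_v,
            "n_match": n_m,
            "concordance": c_s,
            "mean_depth": mean_depth,
        }
    )
    return df.merge(false_positive_rate(calls, chip, qc), on="sample_id", how="left")


def depth_stratum(depth: np.ndarray) -> np.ndarray:
    """Labels '<5x', '5-10x', '>10x' for per-sample mean depths."""
    labels = np.empty(len(depth), dtype=object)
    names = ("<5x", "5-10x", ">10x")
    for (lo, hi), name in zip(DEPTH_STRATA, names):
        labels[(depth >= lo) & (depth < hi)] = name
    return labels


# ---------------------------------------------------------------------------
# site finding and the discovery model
# ---------------------------------------------------------------------------


def site_discovery_table(
    calls: CallSet, chip: ChipDataset, qc: MarkerQCReport
) -> pd.DataFrame:
    """Per chip-variant-site discovery record.

    One row per surviving, chip-polymorphic marker present in the call
    set: chip minor-allele count and frequency, the number of carrier
    samples (>= 1 chip alternate allele), and whether the caller flagged
    the site as variant.
    """
    use = qc.surviving_mask & ~qc.monomorphic_mask & (qc.call_column >= 0)
    cols = np.flatnonzero(use)
    if cols.size == 0:
        raise EmptyInputError("no surviving polymorphic markers")
    chip_rows = [chip.genotypes.sample_ids.index(s) for s in qc.shared_samples]
    g = chip.genotypes.genotypes[np.ix_(chip_rows, cols)]
    nonmiss = g != MISSING
    n_alleles = 2 * nonmiss.sum(axis=0)
    alt_count = np.where(nonmiss, g, 0).sum(axis=0)
    mac = np.minimum(alt_count, n_alleles - alt_count)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(n_alleles > 0, mac / np.maximum(n_alleles, 1), np.nan)
    carriers = ((g == 1) | (g == 2)).sum(axis=0)
    found = calls.site_variant_flag[qc.call_column[cols]]
    return pd.DataFrame(
        {
            "position": chip.genotypes.positions[cols],
            "marker_index": cols,
            "mac": mac,
            "maf": maf,
            "carriers": carriers,
            "found": found,
        }
    )


def default_frequency_bins(n_samples: int) -> list[tuple[str, float, float]]:
    """MAC-1 and MAC-2 bins, then MAF intervals up to 0.5."""
    mac2 = 2.0 / (2 * n_samples)
    edges = [e for e in (0.01, 0.05, 0.5) if e > mac2]
    bins: list[tuple[str, float, float]] = [("MAC=1", 0.0, 0.0), ("MAC=2", 0.0, 0.0)]
    lo = mac2
    for hi in edges:
        bins.append((f"({lo:.4g}, {hi:.4g}]", lo, hi))
        lo = hi
    return bins


def site_finding(
    calls: CallSet,
    chip: ChipDataset,
    qc: MarkerQCReport,
    bins: list[tuple[str, float, float]] | None = None,
) -> pd.DataFrame:
    """Found-fraction of chip variant sites per frequency bin.

    The two lowest bins are minor-allele-count 1 and 2; the rest bin by
    chip minor-allele frequency.  Empty bins report NaN, not 0.
    """
    table = site_discovery_table(calls, chip, qc)
    if bins is None:
        bins = default_frequency_bins(len(qc.shared_samples))
    rows = []
    for label, lo, hi in bins:
        if label == "MAC=1":
            mask = table.mac == 1
        elif label == "MAC=2":
            mask = table.mac == 2
        else:
            mask = (table.mac > 2) & (table.maf > lo) & (table.maf <= hi)
        sub = table[mask]
        frac = sub.found.mean() if len(sub) else np.nan
        rows.append((label, lo, hi, len(sub), int(sub.found.sum()), frac))
    return pd.DataFrame(
        rows, columns=["bin", "maf_low", "maf_high", "n_sites", "n_found", "found_fraction"]
    )


def fit_discovery_model(
    found_flags: np.ndarray,
    carrier_counts: np.ndarray,
) -> float:
    """Maximum-likelihood per-sample discovery probability p.

    Observations are independent Bernoulli with success probability
    1 - (1-p)^f per site, f being the site's carrier count; sites with
    f = 0 are ignored, and all-f=0 input is an error.
    """
    found = np.asarray(found_flags, dtype=bool)
    f = np.asarray(carrier_counts, dtype=float)
    if found.shape != f.shape:
        raise DimensionError("found_flags and carrier_counts length mismatch")
    keep = f >= 1
    if not np.any(keep):
        raise EmptyInputError("need at least one site with carrier count >= 1")
    found, f = found[keep], f[keep]

    def nll(p: float) -> float:
        p = min(max(p, 1e-12), 1 - 1e-12)
        log_miss = f * math.log1p(-p)
        with np.errstate(divide="ignore"):
            log_hit = np.log1p(-np.exp(log_miss))
        return -float(np.where(found, log_hit, log_miss).sum())

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded")
    return float(np.clip(res.x, 0.0, 1.0))


@dataclass
class DiscoveryModelFit:
    """Binned found-fractions with the fitted 1-(1-p)^f curve."""

    bin_table: pd.DataFrame
    p_hat: float
    max_abs_residual: float


def discovery_model_report(
    calls: CallSet,
    chip: ChipDataset,
    qc: MarkerQCReport,
    bins: list[tuple[str, float, float]] | None = None,
) -> DiscoveryModelFit:
    """Fit the constant-p discovery model and compare it per frequency bin."""
    table = site_discovery_table(calls, chip, qc)
    p_hat = fit_discovery_model(table.found.to_numpy(), table.carriers.to_numpy())
    table["predicted"] = 1.0 - (1.0 - p_hat) ** table.carriers.clip(lower=0)
    binned = site_finding(calls, chip, qc, bins=bins)
    predicted = []
    for _, row in binned.iterrows():
        if row.bin == "MAC=1":
            mask = table.mac == 1
        elif row.bin == "MAC=2":
            mask = table.mac == 2
        else:
            mask = (table.mac > 2) & (table.maf > row.maf_low) & (table.maf <= row.maf_high)
        sub = table[mask & (table.carriers >= 1)]
        predicted.append(sub.predicted.mean() if len(sub) else np.nan)
    binned["predicted_fraction"] = predicted
    resid = (binned.found_fraction - binned.predicted_fraction).abs()
    return DiscoveryModelFit(binned, p_hat, float(resid.max(skipna=True)))


# ---------------------------------------------------------------------------
# allele-frequency comparison histograms
# ---------------------------------------------------------------------------


@dataclass
class FrequencyComparison:
    hist2d: np.ndarray
    edges: np.ndarray
    diff_counts: np.ndarray
    diff_edges: np.ndarray
    n_sites: int


def frequency_comparison(
    freqs_a: np.ndarray, freqs_b: np.ndarray, grid: int = 50
) -> FrequencyComparison:
    """2-D histogram of two per-site non-reference-allele frequency vectors
    plus a 1-D histogram of their differences."""
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if a.shape != b.shape:
        raise DimensionError("frequency vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    edges = np.linspace(0.0, 1.0, grid + 1)
    h2, _, _ = np.histogram2d(a, b, bins=[edges, edges])
    diff_edges = np.linspace(-1.0, 1.0, 2 * grid + 1)
    d, _ = np.histogram(a - b, bins=diff_edges)
    return FrequencyComparison(h2, edges, d, diff_edges, int(a.size))
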