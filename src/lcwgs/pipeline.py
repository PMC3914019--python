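"""End-to-end experiment orchestration.

simulate -> call (single, multi, LD-aware) -> marker QC -> concordance /
false-positive rate / site finding -> identity matching -> kinship and
BLUE allele frequencies.  Deterministic for a fixed config: the master
seed derives one seed per stage by stage-name hashing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import callers, evaluate, identity, io, kinship, simulate
from ._utils import derive_seed
from .config import RunConfig


@dataclass
class SimulatedCohort:
    pedigree: simulate.PedigreeTable
    truth_all: simulate.HaplotypePanel
    cohort_ids: list[str]
    truth: simulate.HaplotypePanel          # sequenced subset
    mean_depths: np.ndarray
    pileups: simulate.PileupMatrix
    chip: simulate.ChipDataset


def simulate_cohort(cfg: RunConfig) -> SimulatedCohort:
    """Generate the full synthetic study: pedigree, truth, pileups, chip."""
    ped = simulate.generate_pedigree(
        cfg.n_founders,
        cfg.n_generations,
        mean_offspring=cfg.mean_offspring,
        admixture_fraction=cfg.admixture_fraction,
        seed=derive_seed(cfg.seed, "pedigree"),
        second_union_prob=cfg.second_union_prob,
    )
    panel = simulate.simulate_admixed_founder_panel(
        ped,
        cfg.n_sites,
        n_seed_haplotypes=cfg.n_seed_haplotypes,
        switch_rate=cfg.switch_rate,
        mutation_rate=cfg.mutation_rate,
        freq_offset_scale=cfg.freq_offset_scale,
        min_minor_count=cfg.min_minor_count,
        seed=derive_seed(cfg.seed, "founders"),
    )
    truth_all = simulate.gene_drop(
        ped, panel, recomb_rate=cfg.recomb_rate, seed=derive_seed(cfg.seed, "genedrop")
    )

    rng = np.random.default_rng(derive_seed(cfg.seed, "cohort"))
    n_seq = min(cfg.n_sequenced, ped.n)
    idx = np.sort(rng.choice(ped.n, size=n_seq, replace=False))
    cohort_ids = [ped.individual_id[i] for i in idx]
    truth = truth_all.subset_samples(cohort_ids)

    mean_depths = rng.uniform(cfg.depth_low, cfg.depth_high, size=n_seq)
    pileups = simulate.simulate_pileups(
        truth, mean_depths, base_error=cfg.base_error, seed=derive_seed(cfg.seed, "pileups")
    )

    n_markers = max(1, int(round(cfg.chip_marker_fraction * cfg.n_sites)))
    markers = np.sort(rng.choice(cfg.n_sites, size=n_markers, replace=False))
    chip = simulate.simulate_chip(
        truth,
        markers,
        genotyping_error=cfg.genotyping_error,
        missing_rate=cfg.chip_missing_rate,
        flip_fraction=cfg.flip_fraction,
        n_duplicates=cfg.n_duplicates,
        seed=derive_seed(cfg.seed, "chip"),
    )
    return SimulatedCohort(ped, truth_all, cohort_ids, truth, mean_depths, pileups, chip)


def run_callers(cohort: SimulatedCohort, cfg: RunConfig) -> dict[str, callers.CallSet]:
    return {
        "single": callers.call_single_sample(
            cohort.pileups, cfg.base_error, cfg.min_call_quality
        ),
        "multi": callers.call_multi_sample(
            cohort.pileups, cfg.base_error, cfg.min_site_quality
        ),
        "ld": callers.call_ld_aware(
            cohort.pileups,
            cfg.base_error,
            n_rounds=cfg.n_rounds,
            n_templates=cfg.n_templates,
            recomb_switch=cfg.recomb_switch,
            template_error=cfg.template_error,
            seed=derive_seed(cfg.seed, "ld_caller"),
        ),
    }


@dataclass
class ExperimentResult:
    cohort: SimulatedCohort
    calls: dict[str, callers.CallSet]
    qc: evaluate.MarkerQCReport
    concordance: dict[str, pd.DataFrame]
    site_finding: dict[str, pd.DataFrame]
    discovery_fit: evaluate.DiscoveryModelFit
    match: identity.MatchMatrix
    kin_pedigree: kinship.KinshipMatrix
    kin_empirical: kinship.KinshipMatrix
    kin_histograms: pd.DataFrame
    frequencies: kinship.FrequencyEstimate
    subset_ids: list[str]
    subset_correlation: float
    summary: dict = field(default_factory=dict)


def _summary(result: "ExperimentResult") -> dict:
    out: dict = {"n_samples": len(result.cohort.cohort_ids)}
    for method, df in result.concordance.items():
        stratum = evaluate.depth_stratum(df.mean_depth.to_numpy())
        out[f"median_concordance_{method}"] = float(df.concordance.median())
        out[f"median_fpr_{method}"] = float(df.fpr.median())
        for name in ("<5x", "5-10x", ">10x"):
            sub = df[stratum == name]
            out[f"median_concordance_{method}_{name}"] = float(sub.concordance.median())
    for method, df in result.site_finding.items():
        mac1 = df[df.bin == "MAC=1"]
        if len(mac1):
            out[f"singleton_found_fraction_{method}"] = float(
                mac1.found_fraction.iloc[0]
            )
    out["discovery_p_hat"] = result.discovery_fit.p_hat
    out["discovery_max_bin_residual"] = result.discovery_fit.max_abs_residual
    out["n_flipped_removed"] = int(len(result.qc.flipped_removed))
    out["n_hwe_removed"] = int(len(result.qc.hwe_removed))
    out["n_dup_removed"] = int(len(result.qc.dup_discordant_removed))
    out["n_identity_flags"] = len(result.match.mismatch_flags)
    out["rms_blue_correction"] = result.frequencies.rms_correction
    out["subset_correction_correlation"] = result.subset_correlation
    return out


def run_experiment(cfg: RunConfig, write: bool = True) -> ExperimentResult:
    """Run the full analysis and (optionally) write the report bundle."""
    cohort = simulate_cohort(cfg)
    calls = run_callers(cohort, cfg)

    # marker QC: flip filter needs calls; use the LD-aware set (the highest-
    # concordance caller), HWE on a pedigree-unrelated subset
    kin_ped_all = kinship.pedigree_kinship(cohort.pedigree)
    kin_ped = kin_ped_all.submatrix(cohort.cohort_ids)
    unrelated = kinship.unrelated_subset(kin_ped, cfg.unrelated_kinship_threshold)
    qc = evaluate.filter_markers(
        cohort.chip,
        calls["ld"],
        hwe_threshold=cfg.hwe_threshold,
        flip_threshold=cfg.flip_threshold,
        dup_max_discordant=cfg.dup_max_discordant,
        unrelated_samples=unrelated,
    )

    concordance = {
        m: evaluate.sample_concordance(c, cohort.chip, qc) for m, c in calls.items()
    }
    site_finding = {
        m: evaluate.site_finding(c, cohort.chip, qc) for m, c in calls.items()
    }
    discovery_fit = evaluate.discovery_model_report(calls["single"], cohort.chip, qc)

    match = identity.match_samples(calls["single"], cohort.chip, freq_floor=cfg.freq_floor)

    ld_genotypes = calls["ld"].genotypes
    kin_emp = kinship.empirical_kinship(ld_genotypes)
    kin_hist = kinship.kinship_histograms(
        kin_emp, kin_ped, pedigree_values=[0.0, 0.0625, 0.125, 0.25]
    )

    freqs = kinship.blue_frequencies(ld_genotypes, kin_ped)
    subset_ids = unrelated
    sub_gm = ld_genotypes.subset_samples(subset_ids)
    subset_freqs = sub_gm.allele_frequencies()
    subset_dev = subset_freqs - freqs.naive
    corr_mask = np.isfinite(subset_dev) & np.isfinite(freqs.correction)
    if corr_mask.sum() >= 3 and np.std(freqs.correction[corr_mask]) > 0:
        subset_corr = float(
            np.corrcoef(subset_dev[corr_mask], freqs.correction[corr_mask])[0, 1]
        )
    else:
        subset_corr = float("nan")

    result = ExperimentResult(
        cohort=cohort,
        calls=calls,
        qc=qc,
        concordance=concordance,
        site_finding=site_finding,
        discovery_fit=discovery_fit,
        match=match,
        kin_pedigree=kin_ped,
        kin_empirical=kin_emp,
        kin_histograms=kin_hist,
        frequencies=freqs,
        subset_ids=subset_ids,
        subset_correlation=subset_corr,
    )
    result.summary = _summary(result)
    if write:
        _write_bundle(result, cfg)
    return result


def _write_bundle(result: ExperimentResult, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    io.write_fam(result.cohort.pedigree, out / "pedigree.fam")
    io.write_pileups_tsv(result.cohort.pileups, out / "pileups.tsv")
    io.write_dosage_tsv(result.cohort.chip.genotypes, out / "chip.tsv")
    for method, cs in result.calls.items():
        io.write_vcf(cs, out / f"calls_{method}.vcf")
    for method, df in result.concordance.items():
        df.to_csv(out / f"concordance_{method}.tsv", sep="\t", index=False)
    for method, df in result.site_finding.items():
        df.to_csv(out / f"site_finding_{method}.tsv", sep="\t", index=False)
    result.qc.to_frame().to_csv(out / "marker_qc.tsv", sep="\t", index=False)
    result.match.to_frame().to_csv(out / "identity_matrix.tsv", sep="\t")
    result.match.flag_report().to_csv(out / "identity_flags.tsv", sep="\t", index=False)
    result.kin_pedigree.to_long_frame().to_csv(
        out / "kinship_pedigree.tsv", sep="\t", index=False
    )
    result.kin_empirical.to_long_frame().to_csv(
        out / "kinship_empirical.tsv", sep="\t", index=False
    )
    result.kin_histograms.to_csv(out / "kinship_histograms.tsv", sep="\t", index=False)
    result.frequencies.to_frame().to_csv(out / "frequencies.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
    if cfg.make_plots:
        _make_plots(result, out)


def _make_plots(result: ExperimentResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for method, df in result.concordance.items():
        axes[0].scatter(df.mean_depth, df.concordance, s=8, label=method)
        axes[1].scatter(df.mean_depth, df.fpr, s=8, label=method)
    axes[0].set_xlabel("mean depth")
    axes[0].set_ylabel("concordance $C_S$")
    axes[1].set_xlabel("mean depth")
    axes[1].set_ylabel("false positive rate")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(out / "concordance_vs_depth.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for method, df in result.site_finding.items():
        ax.plot(range(len(df)), df.found_fraction, marker="o", label=method)
    ax.set_xticks(range(len(df)))
    ax.set_xticklabels(df.bin, rotation=30, ha="right")
    ax.set_ylabel("fraction of variant sites found")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "site_finding.png", dpi=120)
    plt.close(fig)
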