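"""Run configuration: one flat dataclass, YAML round-trip, master seed."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Every simulation / calling / evaluation parameter with its default.

    The master seed deterministically derives per-stage seeds (stage-name
    hashing), so stages can be re-run in isolation; a resolved copy of the
    config is written beside every run's outputs.
    """

    # cohort / pedigree
    n_founders: int = 32
    n_generations: int = 3
    mean_offspring: float = 2.2
    admixture_fraction: float = 0.25
    second_union_prob: float = 0.3
    n_sequenced: int = 100          # samples drawn from the pedigree for WGS

    # haplotypes / LD
    n_sites: int = 1000
    n_seed_haplotypes: int = 10
    switch_rate: float = 0.02
    mutation_rate: float = 0.003
    freq_offset_scale: float = 0.1
    min_minor_count: int = 1
    recomb_rate: float = 0.01

    # sequencing
    depth_low: float = 1.0
    depth_high: float = 15.0
    base_error: float = 0.005

    # chip
    chip_marker_fraction: float = 1.0
    genotyping_error: float = 0.001
    chip_missing_rate: float = 0.005
    flip_fraction: float = 0.005
    n_duplicates: int = 5

    # callers
    min_call_quality: float = 4.0
    min_site_quality: float = 4.0
    n_rounds: int = 20
    n_templates: int = 40
    recomb_switch: float = 0.01
    template_error: float = 0.01

    # evaluation / QC
    hwe_threshold: float = 1e-10
    flip_threshold: float = 0.02
    dup_max_discordant: int = 3
    unrelated_kinship_threshold: float = 0.1

    # identity
    freq_floor: float = 1e-4

    # run
    seed: int = 0
    out_dir: str = "lcwgs_run"
    log_level: str = "INFO"
    make_plots: bool = False

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
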