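"""Shared fixtures: hand-built pedigrees and a planted-artifact chip."""

from __future__ import annotations

import numpy as np
import pytest

from lcwgs.callers import CallSet
from lcwgs.pedigrees import textbook_pedigree, unbalanced_pedigree
from lcwgs.simulate import ChipDataset, GenotypeMatrix, PedigreeTable


@pytest.fixture
def textbook_ped() -> PedigreeTable:
    return textbook_pedigree()


@pytest.fixture
def unbalanced_ped() -> PedigreeTable:
    return unbalanced_pedigree()


def planted_artifact_chip() -> tuple[ChipDataset, CallSet, dict[str, int]]:
    """Chip with one flipped, one duplicate-discordant and one extreme-HWE
    marker planted among clean markers, plus a perfectly matching call set.

    Returns (chip, calls, markers) where markers maps artifact name to
    marker index.  Marker 'dup_ok' is discordant in exactly three duplicate
    pairs and must survive the duplicate filter.
    """
    rng = np.random.default_rng(42)
    n_samples, n_markers = 50, 20
    markers = {"flip": 3, "dup_bad": 7, "hwe": 11, "dup_ok": 15}

    truth = rng.binomial(2, 0.3, size=(n_samples, n_markers)).astype(np.int8)
    truth[:, markers["flip"]] = 0          # monomorphic in truth
    truth[:, markers["hwe"]] = 1           # every sample heterozygous

    chip_g = truth.copy()
    chip_g[:, markers["flip"]] = 2 - chip_g[:, markers["flip"]]  # A/B reversal

    sample_ids = [f"S{i:02d}" for i in range(n_samples)]
    dup_src = [0, 1, 2, 3, 4]
    dup_ids = [f"{sample_ids[i]}_dup" for i in dup_src]
    dup_g = chip_g[dup_src].copy()
    dup_g[:4, markers["dup_bad"]] = (dup_g[:4, markers["dup_bad"]] + 1) % 3
    dup_g[:3, markers["dup_ok"]] = (dup_g[:3, markers["dup_ok"]] + 1) % 3

    positions = np.arange(1, n_markers + 1) * 1000
    ref = np.array(["A"] * n_markers)
    alt = np.array(["C"] * n_markers)
    gm = GenotypeMatrix(
        np.vstack([chip_g, dup_g]), sample_ids + dup_ids, positions, ref, alt
    )
    chip = ChipDataset(
        genotypes=gm,
        flipped_mask=np.arange(n_markers) == markers["flip"],
        duplicate_pairs=list(zip([sample_ids[i] for i in dup_src], dup_ids)),
    )

    call_gm = GenotypeMatrix(truth.copy(), sample_ids, positions, ref, alt)
    flag = np.any(truth > 0, axis=0)
    calls = CallSet(call_gm, flag, np.zeros(n_markers))
    return chip, calls, markers


@pytest.fixture
def artifact_chip():
    return planted_artifact_chip()
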