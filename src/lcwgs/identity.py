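"""Sample-identity verification between sequencing calls and chip genotypes.

For a WGS sample with PL-encoded genotype likelihoods and a chip sample
with genotypes GT, the match statistic is

    M = prod over markers of L{D | GT_chip} * f_GT

where f_GT is the cohort frequency of the chip genotype class at that
marker.  M is maximized when the two samples are the same individual.
Everything is computed in log10 (the raw product underflows immediately at
realistic marker counts), and a per-marker-normalized value is used for
cross-pair comparison since different WGS samples have informative PLs at
different marker subsets; raw sums are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import EmptyInputError, check
from .callers import CallSet
from .evaluate import _align_markers
from .simulate import MISSING, ChipDataset

DEFAULT_FREQ_FLOOR = 1e-4


def chip_genotype_frequencies(chip: ChipDataset) -> np.ndarray:
    """Per-marker genotype-class frequencies (hom-ref, het, hom-alt).

    Estimated from the chip data itself over non-missing genotypes; markers
    with no data get a uniform triple.
    """
    g = chip.genotypes.genotypes
    counts = np.stack([(g == k).sum(axis=0) for k in (0, 1, 2)], axis=1).astype(float)
    total = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(total > 0, counts / np.maximum(total, 1), 1.0 / 3.0)
    return freqs


def match_statistic(
    pl_triples: np.ndarray,
    chip_genotypes: np.ndarray,
    genotype_freqs: np.ndarray,
    freq_floor: float = DEFAULT_FREQ_FLOOR,
) -> tuple[float, float, int]:
    """log10 M for one (WGS sample, chip sample) pair.

    Sums -PL(GT_chip)/10 + log10 f_GT over markers with a non-missing chip
    genotype; f_GT is floored at ``freq_floor`` so empty genotype classes
    do not contribute -infinity.  Returns (raw log10 M, per-marker
    normalized log10 M, markers used).
    """
    pl = np.asarray(pl_triples, dtype=float)
    gt = np.asarray(chip_genotypes)
    freqs = np.asarray(genotype_freqs, dtype=float)
    check(pl.ndim == 2 and pl.shape[1] == 3, "pl_triples must be (n_markers, 3)")
    check(gt.shape[0] == pl.shape[0] == freqs.shape[0], "marker count mismatch")
    usable = gt != MISSING
    if not np.any(usable):
        raise EmptyInputError("no marker with both a PL triple and a chip genotype")
    idx = np.flatnonzero(usable)
    g = gt[idx].astype(np.int64)
    terms = -pl[idx, g] / 10.0 + np.log10(np.maximum(freqs[idx, g], freq_floor))
    raw = float(terms.sum())
    return raw, raw / idx.size, int(idx.size)


@dataclass
class MatchMatrix:
    """All-pairs identity scores and the resulting pairing diagnosis."""

    log10_m: np.ndarray          # normalized per marker used
    log10_m_raw: np.ndarray
    markers_used: np.ndarray
    wgs_samples: list[str]
    chip_samples: list[str]
    best_match: list[str]
    tied: list[bool]
    mismatch_flags: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.log10_m, index=self.wgs_samples, columns=self.chip_samples
        )

    def flag_report(self) -> pd.DataFrame:
        rows = []
        for j, cs in enumerate(self.chip_samples):
            rows.append(
                (cs, self.best_match[j], self.tied[j], cs in set(self.mismatch_flags))
            )
        return pd.DataFrame(
            rows, columns=["chip_sample", "best_wgs_match", "tied", "flagged"]
        )


def match_samples(
    calls: CallSet,
    chip: ChipDataset,
    labelled_pairing: dict[str, str] | None = None,
    freq_floor: float = DEFAULT_FREQ_FLOOR,
) -> MatchMatrix:
    """Score every (WGS, chip) sample pair and flag apparent mismatches.

    ``labelled_pairing`` maps chip sample id to its labelled WGS sample id;
    by default each chip sample is paired with the WGS sample of the same
    id (duplicate chip samples with no WGS counterpart are scored but not
    flagged).  A chip sample is flagged when its argmax WGS sample differs
    from the labelled pairing.  Ties in the argmax are reported, not
    silently broken.
    """
    check(len(calls.sample_ids) >= 2, "need >= 2 WGS samples", EmptyInputError)
    check(chip.genotypes.n_samples >= 2, "need >= 2 chip samples", EmptyInputError)
    if calls.pl is None:
        raise EmptyInputError("call set carries no PL annotations")
    col = _align_markers(calls, chip)
    usable_markers = np.flatnonzero(col >= 0)
    freqs = chip_genotype_frequencies(chip)

    wgs = list(calls.sample_ids)
    chips = list(chip.genotypes.sample_ids)
    if labelled_pairing is None:
        labelled_pairing = {c: c for c in chips if c in set(wgs)}

    n_w, n_c = len(wgs), len(chips)
    raw = np.full((n_w, n_c), np.nan)
    norm = np.full((n_w, n_c), np.nan)
    used = np.zeros((n_w, n_c), dtype=np.int64)
    pl = calls.pl.pl
    for j, cs in enumerate(chips):
        gt = chip.genotypes.genotypes[j, usable_markers]
        fr = freqs[usable_markers]
        for i in range(n_w):
            r, nm, k = match_statistic(
                pl[i][col[usable_markers]], gt, fr, freq_floor=freq_floor
            )
            raw[i, j], norm[i, j], used[i, j] = r, nm, k

    best: list[str] = []
    tied: list[bool] = []
    flags: list[str] = []
    for j, cs in enumerate(chips):
        column = norm[:, j]
        top = np.nanmax(column)
        winners = np.flatnonzero(np.isclose(column, top, rtol=0, atol=1e-12))
        best.append(wgs[int(winners[np.argmax(column[winners])])])
        tied.append(len(winners) > 1)
        expected = labelled_pairing.get(cs)
        if expected is not None and expected != best[-1]:
            flags.append(cs)
    return MatchMatrix(norm, raw, used, wgs, chips, best, tied, flags)
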