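"""Readers and writers for the interchange formats.

VCF v4.2 (GT:DP:PL, biallelic SNPs only) for call sets and genotype
matrices, PLINK .fam for pedigrees, TSV for dosage matrices and pileups.
Reading goes through cyvcf2; writing emits plain-text VCF.  All formats
round-trip: read(write(x)) == x for the fields each format carries.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from ._utils import EmptyInputError
from .callers import PL_CAP, CallSet, LikelihoodSet
from .simulate import MISSING, GenotypeMatrix, PedigreeTable, PileupMatrix

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(calls: CallSet, path: str | Path, contig: str = "1") -> None:
    """Write a call set as VCF v4.2 with GT:DP:PL sample fields."""
    path = Path(path)
    gm = calls.genotypes
    has_pl = calls.pl is not None
    has_dp = calls.depth is not None
    fmt = "GT" + (":DP" if has_dp else "") + (":PL" if has_pl else "")
    length = int(gm.positions[-1]) + 1 if gm.n_sites else 1
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if has_dp:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    if has_pl:
        lines.append(
            '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">'
        )
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(
        gm.sample_ids
    )
    lines.append(header)
    for s in range(gm.n_sites):
        qual = calls.call_quality[s]
        qual_str = f"{qual:.2f}" if np.isfinite(qual) else "."
        fields = [
            contig,
            str(int(gm.positions[s])),
            ".",
            str(gm.ref_allele[s]),
            str(gm.alt_allele[s]),
            qual_str,
            "PASS",
            ".",
            fmt,
        ]
        for i in range(gm.n_samples):
            parts = [_GT_STRINGS[int(gm.genotypes[i, s])]]
            if has_dp:
                parts.append(str(int(calls.depth[i, s])))
            if has_pl:
                parts.append(",".join(str(int(v)) for v in calls.pl.pl[i, s]))
            fields.append(":".join(parts))
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> CallSet:
    """Read a biallelic-SNP VCF into a CallSet.

    Parses GT plus PL and DP when present.  Multi-allelic or non-SNP
    records (indels) are skipped with a counted warning.  1-based positions
    are preserved.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    quals: list[float] = []
    gts: list[np.ndarray] = []
    pls: list[np.ndarray | None] = []
    dps: list[np.ndarray | None] = []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        g = np.array([a + b if a >= 0 and b >= 0 else MISSING
                      for a, b, *_ in v.genotypes], dtype=np.int8)
        gts.append(g)
        try:
            pl = v.format("PL")
        except KeyError:
            pl = None
        pls.append(None if pl is None else np.asarray(pl, dtype=np.int64))
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        dps.append(None if dp is None else np.asarray(dp, dtype=np.int64).ravel())
    if skipped:
        warnings.warn(f"skipped {skipped} non-SNP or multi-allelic record(s)")
    if not positions:
        raise EmptyInputError(f"no usable biallelic SNP records in {path}")

    genotypes = np.stack(gts, axis=1)
    gm = GenotypeMatrix(
        genotypes=genotypes,
        sample_ids=samples,
        positions=np.array(positions, dtype=np.int64),
        ref_allele=np.array(refs),
        alt_allele=np.array(alts),
    )
    lset = None
    if all(p is not None for p in pls):
        pl_arr = np.stack(pls, axis=1)  # (n_samples, n_sites, 3)
        pl_arr = np.clip(pl_arr - pl_arr.min(axis=2, keepdims=True), 0, PL_CAP)
        lset = LikelihoodSet(pl_arr.astype(np.int16), samples, gm.positions.copy())
    depth = None
    if all(d is not None for d in dps):
        depth = np.stack(dps, axis=1)
    flag = np.any((genotypes > 0) & (genotypes != MISSING), axis=0)
    return CallSet(gm, flag, np.array(quals, dtype=float), pl=lset, depth=depth)


def genotype_matrix_to_callset(gm: GenotypeMatrix) -> CallSet:
    """Wrap a bare genotype matrix (e.g. chip data) as a CallSet for writing."""
    flag = np.any((gm.genotypes > 0) & (gm.genotypes != MISSING), axis=0)
    return CallSet(gm, flag, np.full(gm.n_sites, np.nan))


# ---------------------------------------------------------------------------
# dosage TSV (sites x samples)
# ---------------------------------------------------------------------------


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    values = gm.genotypes.T.astype(object)
    values[values == MISSING] = pd.NA
    df = pd.DataFrame(values, columns=gm.sample_ids)
    df.insert(0, "position", gm.positions)
    df.insert(1, "ref", gm.ref_allele)
    df.insert(2, "alt", gm.alt_allele)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta = ["position", "ref", "alt"]
    samples = [c for c in df.columns if c not in meta]
    if not samples or df.empty:
        raise EmptyInputError(f"no usable dosage records in {path}")
    g = df[samples].to_numpy(dtype=float)
    g = np.where(np.isnan(g), MISSING, g).astype(np.int8).T
    return GenotypeMatrix(
        genotypes=g,
        sample_ids=samples,
        positions=df["position"].to_numpy(dtype=np.int64),
        ref_allele=df["ref"].to_numpy(dtype=object),
        alt_allele=df["alt"].to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------------
# PLINK .fam
# ---------------------------------------------------------------------------


def write_fam(pedigree: PedigreeTable, path: str | Path, family_id: str = "FAM1") -> None:
    """PLINK .fam dialect: FID IID PAT MAT SEX PHENO, 0 = missing parent."""
    rows = []
    for i, iid in enumerate(pedigree.individual_id):
        rows.append(
            (
                family_id,
                iid,
                pedigree.father_id[i] or "0",
                pedigree.mother_id[i] or "0",
                int(pedigree.sex[i]),
                -9,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_fam(path: str | Path) -> PedigreeTable:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    if df.empty:
        raise EmptyInputError(f"empty .fam file {path}")
    fathers = [None if p == "0" else p for p in df.pat]
    mothers = [None if p == "0" else p for p in df.mat]
    pops = [None] * len(df)
    return PedigreeTable(
        list(df.iid), fathers, mothers, df.sex.astype(int).to_numpy(), pops
    )


# ---------------------------------------------------------------------------
# pileup TSV
# ---------------------------------------------------------------------------


def write_pileups_tsv(pileups: PileupMatrix, path: str | Path) -> None:
    n, s = pileups.ref_count.shape
    sample = np.repeat(pileups.sample_ids, s)
    df = pd.DataFrame(
        {
            "sample_id": sample,
            "site_index": np.tile(np.arange(s), n),
            "position": np.tile(pileups.positions, n),
            "ref_allele": np.tile(pileups.ref_allele, n),
            "alt_allele": np.tile(pileups.alt_allele, n),
            "ref_count": pileups.ref_count.ravel(),
            "alt_count": pileups.alt_count.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pileups_tsv(path: str | Path) -> PileupMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise EmptyInputError(f"no pileup records in {path}")
    samples = list(dict.fromkeys(df.sample_id))
    sites = df[df.sample_id == samples[0]].sort_values("site_index")
    n, s = len(samples), len(sites)
    ref = np.empty((n, s), dtype=np.int32)
    alt = np.empty((n, s), dtype=np.int32)
    for i, sid in enumerate(samples):
        sub = df[df.sample_id == sid].sort_values("site_index")
        ref[i] = sub.ref_count.to_numpy()
        alt[i] = sub.alt_count.to_numpy()
    return PileupMatrix(
        ref_count=ref,
        alt_count=alt,
        sample_ids=[str(x) for x in samples],
        positions=sites.position.to_numpy(dtype=np.int64),
        ref_allele=sites.ref_allele.to_numpy(dtype=object),
        alt_allele=sites.alt_allele.to_numpy(dtype=object),
    )
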