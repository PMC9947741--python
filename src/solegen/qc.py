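"""SNP and sample quality control for allele-dosage genotype matrices.

Filters follow the conventional preprocessing order for single-step genomic
evaluations: SNP call rate, minor allele frequency, monomorphism, and
Hardy-Weinberg deviation (absolute difference between observed and expected
heterozygote frequency); then sample call rate and parent-progeny Mendelian
conflict (opposing-homozygote) rate against a pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "QCReport", "snp_filters", "sample_filters"]


@dataclass
class GenotypeMatrix:
    """Animals x SNPs allele dosages in {0, 1, 2}, NaN for missing calls."""

    dosages: np.ndarray
    animal_ids: np.ndarray
    snp_map: pd.DataFrame  # columns: chrom, pos, snp_id

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.animal_ids = np.asarray(self.animal_ids)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (animals x SNPs)")
        n, m = self.dosages.shape
        if len(self.animal_ids) != n:
            raise ValueError("animal_ids length does not match dosage rows")
        if len(self.snp_map) != m:
            raise ValueError("snp_map length does not match dosage columns")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosage codes must be 0/1/2 or missing")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset(self, animal_mask=None, snp_mask=None) -> "GenotypeMatrix":
        a = slice(None) if animal_mask is None else animal_mask
        s = slice(None) if snp_mask is None else snp_mask
        return GenotypeMatrix(
            self.dosages[a][:, s],
            self.animal_ids[a],
            self.snp_map.iloc[s].reset_index(drop=True),
        )

    def call_rates(self, axis: int) -> np.ndarray:
        """Fraction of non-missing calls per SNP (axis=0) or animal (axis=1)."""
        return 1.0 - np.isnan(self.dosages).mean(axis=axis)

    def allele_frequencies(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class QCReport:
    n_snps_in: int = 0
    n_animals_in: int = 0
    removed_snp_call_rate: int = 0
    removed_maf: int = 0
    removed_monomorphic: int = 0
    removed_hwe: int = 0
    removed_sample_call_rate: int = 0
    removed_mendelian_conflict: int = 0
    n_snps_out: int = 0
    n_animals_out: int = 0
    conflict_rates: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "conflict_rates"}
        d["conflict_rates"] = {str(k): float(v) for k, v in self.conflict_rates.items()}
        return d


def snp_filters(
    G: GenotypeMatrix,
    call_rate_min: float = 0.90,
    maf_min: float = 0.05,
    hwe_dev_max: float = 0.15,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs failing, in order: call rate, MAF, monomorphism, HWE.

    HWE deviation is |observed heterozygote frequency - 2p(1-p)| computed on
    the SNPs surviving the earlier stages. Returns the filtered matrix and a
    per-stage removal report.
    """
    if G.n_snps == 0 or G.n_animals == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport(n_snps_in=G.n_snps, n_animals_in=G.n_animals)

    keep = G.call_rates(axis=0) >= call_rate_min
    report.removed_snp_call_rate = int((~keep).sum())
    G = G.subset(snp_mask=keep)

    p = G.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    # monomorphic SNPs (maf == 0) fall through to their own stage
    keep = (maf >= maf_min) | (maf == 0.0)
    report.removed_maf = int((~keep).sum())
    G = G.subset(snp_mask=keep)

    p = G.allele_frequencies()
    keep = (p > 0.0) & (p < 1.0)
    report.removed_monomorphic = int((~keep).sum())
    G = G.subset(snp_mask=keep)

    p = G.allele_frequencies()
    with np.errstate(invalid="ignore"):
        obs_het = np.nanmean(G.dosages == 1.0, axis=0)
    exp_het = 2.0 * p * (1.0 - p)
    keep = np.abs(obs_het - exp_het) <= hwe_dev_max
    report.removed_hwe = int((~keep).sum())
    G = G.subset(snp_mask=keep)

    report.n_snps_out = G.n_snps
    report.n_animals_out = G.n_animals
    return G, report


def _opposing_homozygote_rate(parent: np.ndarray, progeny: np.ndarray) -> float:
    both = ~np.isnan(parent) & ~np.isnan(progeny)
    if not both.any():
        return np.nan
    opposing = ((parent == 0.0) & (progeny == 2.0)) | ((parent == 2.0) & (progeny == 0.0))
    return float(opposing[both].sum() / both.sum())


def sample_filters(
    G: GenotypeMatrix,
    pedigree: pd.DataFrame,
    call_rate_min: float = 0.90,
    conflict_rate_max: float = 0.02,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove animals with low call rate or excess parent-progeny conflicts.

    ``pedigree`` needs columns animal/sire/dam (0 = unknown). For every
    genotyped parent-progeny pair the opposing-homozygote rate over SNPs
    with both calls present is computed; progeny above ``conflict_rate_max``
    are removed. With no genotyped pairs the conflict check is skipped.
    """
    if G.n_snps == 0 or G.n_animals == 0:
        raise ValueError("empty genotype matrix")
    report = QCReport(n_snps_in=G.n_snps, n_animals_in=G.n_animals)

    keep = G.call_rates(axis=1) >= call_rate_min
    report.removed_sample_call_rate = int((~keep).sum())
    G = G.subset(animal_mask=keep)

    idx = {a: i for i, a in enumerate(G.animal_ids)}
    conflicted: set = set()
    for row in pedigree.itertuples(index=False):
        child = getattr(row, "animal")
        if child not in idx:
            continue
        for parent in (getattr(row, "sire"), getattr(row, "dam")):
            if parent and parent in idx:
                rate = _opposing_homozygote_rate(
                    G.dosages[idx[parent]], G.dosages[idx[child]]
                )
                if np.isnan(rate):
                    continue
                report.conflict_rates[(parent, child)] = rate
                if rate > conflict_rate_max:
                    conflicted.add(child)
    keep = ~np.isin(G.animal_ids, list(conflicted))
    report.removed_mendelian_conflict = int((~keep).sum())
    G = G.subset(animal_mask=keep)

    report.n_snps_out = G.n_snps
    report.n_animals_out = G.n_animals
    return G, report
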