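"""Plain-text readers and writers for the pipeline's file formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .lesions import CohortRecords
from .kinship import Pedigree
from .qc import GenotypeMatrix

__all__ = [
    "read_pedigree_csv",
    "write_pedigree_csv",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_plink",
    "write_plink",
    "read_records_csv",
    "write_records_csv",
    "write_matrix_coo",
]


def write_pedigree_csv(pedigree: Pedigree, path) -> None:
    pedigree.to_frame().to_csv(path, index=False)


def read_pedigree_csv(path) -> Pedigree:
    return Pedigree.from_frame(pd.read_csv(path))


def write_genotype_tsv(G: GenotypeMatrix, path) -> None:
    """Animals x SNPs dosage matrix, first column = animal id, NA = missing."""
    frame = pd.DataFrame(
        G.dosages, index=pd.Index(G.animal_ids, name="animal"), columns=G.snp_map["snp_id"]
    )
    frame.to_csv(path, sep="\t", na_rep="NA")


def read_genotype_tsv(path, snp_map: pd.DataFrame | None = None) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if snp_map is None:
        snp_map = pd.DataFrame(
            {"chrom": 0, "pos": 0, "snp_id": frame.columns.to_numpy()}
        )
    return GenotypeMatrix(frame.to_numpy(dtype=float), frame.index.to_numpy(), snp_map)


def write_plink(G: GenotypeMatrix, prefix) -> None:
    """PLINK text .ped/.map; dosage = count of allele B, missing = '0 0'."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for row in G.snp_map.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\n")
    codes = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, animal in enumerate(G.animal_ids):
            geno = "\t".join(
                "0 0" if np.isnan(d) else codes[d] for d in G.dosages[i]
            )
            fh.write(f"{animal}\t{animal}\t0\t0\t0\t-9\t{geno}\n")


def read_plink(prefix) -> GenotypeMatrix:
    """Read PLINK text .ped/.map; dosage counts the later-sorted allele."""
    prefix = Path(prefix)
    snp_map = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
    )[["chrom", "pos", "snp_id"]]
    animals, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            animals.append(parts[1])
            alleles = parts[6:]
            rows.append([(alleles[2 * j], alleles[2 * j + 1]) for j in range(len(alleles) // 2)])
    m = len(snp_map)
    dosage = np.full((len(animals), m), np.nan)
    for j in range(m):
        observed = sorted(
            {a for row in rows for a in row[j] if a != "0"}
        )
        if not observed:
            continue
        alt = observed[-1]
        for i, row in enumerate(rows):
            a1, a2 = row[j]
            if a1 != "0" and a2 != "0":
                dosage[i, j] = (a1 == alt) + (a2 == alt)
    ids = np.array(animals)
    if all(a.isdigit() for a in animals):
        ids = ids.astype(int)
    return GenotypeMatrix(dosage, ids, snp_map)


_CLAW_SEP = "_"


def write_records_csv(records: CohortRecords, path) -> None:
    """Merged long records CSV: one row per claw observation, with the
    assessment metadata (mobility, herd, parity, hys, days) repeated."""
    claws = records.claws.copy()
    claws["claw_id"] = (
        claws["limb"] + _CLAW_SEP + claws["side"] + _CLAW_SEP + claws["claw"]
    )
    merged = claws.merge(records.assessments, on=["animal", "timepoint"], how="left")
    cols = [
        "animal", "herd", "parity", "hys", "timepoint",
        "days_from_calving", "mobility", "claw_id", "grade",
    ]
    merged[[c for c in cols if c in merged.columns]].to_csv(path, index=False)


def read_records_csv(path) -> CohortRecords:
    merged = pd.read_csv(path)
    parts = merged["claw_id"].str.split(_CLAW_SEP, expand=True)
    claws = pd.DataFrame(
        {
            "animal": merged["animal"],
            "timepoint": merged["timepoint"],
            "limb": parts[0],
            "side": parts[1],
            "claw": parts[2],
            "grade": merged["grade"],
        }
    )
    meta_cols = [
        c for c in ("days_from_calving", "mobility", "herd", "parity", "hys")
        if c in merged.columns
    ]
    assessments = (
        merged[["animal", "timepoint"] + meta_cols]
        .drop_duplicates(["animal", "timepoint"])
        .reset_index(drop=True)
    )
    return CohortRecords(claws, assessments)


def write_matrix_coo(matrix, path, tol: float = 0.0) -> None:
    """Coordinate-format text dump (i, j, value), 1-based, upper triangle."""
    coo = sparse.coo_matrix(matrix)
    with open(path, "w") as fh:
        fh.write("i\tj\tvalue\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            if i <= j and abs(v) > tol:
                fh.write(f"{i + 1}\t{j + 1}\t{v:.12g}\n")
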