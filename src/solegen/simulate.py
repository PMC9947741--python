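"""Synthetic multi-herd dairy cohort with known genetic ground truth.

Emulates the structure of a prospective sole-lesion cohort: a pedigree of
founder dams and widely-used sires (each with a handful of daughters),
gene-dropped SNP genotypes, bivariate liability-scale phenotypes for
sole-lesion susceptibility and recovery, and claw-level lesion records at
four assessment timepoints (8 claws per animal) from which the binary
traits can be re-derived exactly when no records are missing.

Breeding values are simulated through the pedigree (parent average plus a
Mendelian-sampling deviation whose variance shrinks with parental
inbreeding), not from SNP effects; genotypes serve only to estimate
relationships, matching the assumptions of the estimation model. Default
variance components (σ²a = 0.42, σ²hys = 0.25, σ²e = 1.04, liability-scale
h² ≈ 0.25) and marginal prevalences (44% susceptible, 71% recovered) mirror
the susceptibility trait of the study population this generator emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kinship import Pedigree, inbreeding, _mendelian_sampling_variance
from .lesions import CohortRecords, LesionGrade, CLAW_POSITIONS, TIMEPOINTS
from .qc import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_liability_phenotypes",
    "simulate_lesion_records",
    "simulate_cohort",
]

TRAITS = ("SL-Susceptibility", "SL-Recovery")

#: mean (SD) of assessment timing relative to calving, days
TIMEPOINT_DAYS = {"T1": (-56.5, 22.3), "T2": (5.4, 2.9), "T3": (84.0, 13.9), "T4": (199.5, 30.5)}

#: severe-hemorrhage : ulcer ratio among affected claws in early lactation
SEVERITY_RATIO = (457, 131)

#: distribution of the number of affected claws per affected animal
N_CLAWS_AFFECTED_PROBS = (0.74, 0.23, 0.02, 0.01)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth generating conditions for the synthetic cohort."""

    n_founders: int = 2000  # founder dams; one daughter each per generation
    n_generations: int = 1
    daughters_per_sire_range: tuple = (2, 8)  # uniform; mean 5 daughters/sire
    n_snps: int = 800
    founder_maf_range: tuple = (0.05, 0.5)
    true_var_additive: float = 0.42
    true_var_hys: float = 0.25
    true_var_residual: float = 1.04
    n_hys_levels: int = 12
    n_herds: int = 4
    parity_effects: tuple = (0.0, 0.12, 0.25)
    genetic_correlation: float = -0.11
    target_prevalence: tuple = (0.44, 0.71)  # susceptibility, recovery
    intercept_susceptibility: float | None = None
    intercept_recovery: float | None = None
    missing_genotype_rate: float = 0.0
    missing_record_rate: float = 0.0
    genotyped_fraction: float = 1.0
    hind_only_t2_herd: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 1 or self.n_generations < 0:
            raise ConfigurationError("need n_founders >= 1 and n_generations >= 0")
        for v in (self.true_var_additive, self.true_var_hys, self.true_var_residual):
            if v < 0:
                raise ConfigurationError("variances must be non-negative")
        for p in (self.missing_genotype_rate, self.missing_record_rate, self.genotyped_fraction):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("rates must be in [0, 1]")
        if self.n_hys_levels < 1:
            raise ConfigurationError("n_hys_levels must be >= 1")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("founder MAF range must lie within (0, 0.5]")
        lo, hi = self.daughters_per_sire_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("invalid daughters_per_sire_range")
        if len(self.parity_effects) != 3:
            raise ConfigurationError("parity_effects needs 3 values")
        if not -1.0 <= self.genetic_correlation <= 1.0:
            raise ConfigurationError("genetic correlation must be in [-1, 1]")

    @property
    def total_variance(self) -> float:
        return self.true_var_additive + self.true_var_hys + self.true_var_residual

    @property
    def true_h2(self) -> float:
        return self.true_var_additive / self.total_variance

    def intercept(self, trait_index: int) -> float:
        """Liability intercept; by default inverse-normal calibrated so the
        marginal prevalence matches the target (net of the mean parity effect)."""
        override = (self.intercept_susceptibility, self.intercept_recovery)[trait_index]
        if override is not None:
            return override
        sd = np.sqrt(self.total_variance)
        return sd * sps.norm.ppf(self.target_prevalence[trait_index]) - float(
            np.mean(self.parity_effects)
        )

    def rng(self, component: int) -> np.random.Generator:
        """Deterministic sub-stream for one pipeline component."""
        return np.random.default_rng([int(self.seed), component])


@dataclass
class GroundTruth:
    """Generating values underlying the synthetic records."""

    pedigree: Pedigree
    cohort_ids: np.ndarray  # phenotyped animals (last generation)
    breeding_values: np.ndarray  # (n_pedigree, 2) per trait
    hys_effects: np.ndarray  # (n_hys, 2)
    liabilities: np.ndarray  # (n_cohort, 2)
    binary_phenotypes: np.ndarray  # (n_cohort, 2), liability > 0
    metadata: pd.DataFrame  # per cohort animal: herd, parity, hys
    inbreeding: np.ndarray

    def truth_frame(self) -> pd.DataFrame:
        recs = []
        for t, trait in enumerate(TRAITS):
            recs.append(
                pd.DataFrame(
                    {
                        "animal": self.cohort_ids,
                        "trait": trait,
                        "liability": self.liabilities[:, t],
                        "value": self.binary_phenotypes[:, t].astype(int),
                    }
                )
            )
        return pd.concat(recs, ignore_index=True)


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    truth: GroundTruth
    records: CohortRecords


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Simulate a dairy-style pedigree.

    Generation 0 holds ``n_founders`` founder dams. Each later generation
    introduces fresh founder sires, each mated to a uniform-random number
    of dams from the previous generation (one daughter per dam), until
    every dam is used. The returned pedigree is topologically ordered with
    ids 1..N; founders have unknown (0) parents.
    """
    rng = config.rng(1)
    lo, hi = config.daughters_per_sire_range
    rows = []
    next_id = 1
    dams = []
    for _ in range(config.n_founders):
        rows.append((next_id, 0, 0))
        dams.append(next_id)
        next_id += 1
    for _ in range(config.n_generations):
        pool = list(rng.permutation(dams))
        daughters = []
        while pool:
            sire = next_id
            rows.append((sire, 0, 0))
            next_id += 1
            k = int(rng.integers(lo, hi + 1))
            for _ in range(min(k, len(pool))):
                dam = pool.pop()
                rows.append((next_id, sire, dam))
                daughters.append(next_id)
                next_id += 1
        dams = daughters
    frame = pd.DataFrame(rows, columns=["animal", "sire", "dam"])
    return Pedigree.from_frame(frame)


def cohort_animals(pedigree: Pedigree) -> np.ndarray:
    """The phenotyped cohort: animals with a known dam (last generation)."""
    has_dam = pedigree.dam >= 0
    if not has_dam.any():
        return pedigree.ids.copy()
    # daughters that are nobody's parent = final generation
    parent_positions = set(pedigree.sire[pedigree.sire >= 0]) | set(
        pedigree.dam[pedigree.dam >= 0]
    )
    keep = [i for i in np.flatnonzero(has_dam) if i not in parent_positions]
    return pedigree.ids[np.asarray(keep, dtype=int)]


def simulate_genotypes(
    pedigree: Pedigree, config: SimulationConfig
) -> GenotypeMatrix:
    """Gene-drop SNP genotypes down the pedigree.

    Founder genotypes are Hardy-Weinberg draws at allele frequencies
    sampled uniformly from ``founder_maf_range``; each offspring receives
    one allele per parent by Mendelian transmission (an unknown parent
    transmits a population allele). Missing calls are masked at
    ``missing_genotype_rate``.
    """
    rng = config.rng(2)
    n, m = len(pedigree), config.n_snps
    lo, hi = config.founder_maf_range
    p = rng.uniform(lo, hi, size=m)
    dosage = np.empty((n, m), dtype=float)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        pat = (
            rng.random(m) < dosage[s] / 2.0 if s >= 0 else rng.random(m) < p
        ).astype(float)
        mat = (
            rng.random(m) < dosage[d] / 2.0 if d >= 0 else rng.random(m) < p
        ).astype(float)
        if s < 0 and d < 0:
            dosage[i] = rng.binomial(2, p).astype(float)
        else:
            dosage[i] = pat + mat
    if config.missing_genotype_rate > 0:
        mask = rng.random((n, m)) < config.missing_genotype_rate
        dosage[mask] = np.nan
    snp_map = pd.DataFrame(
        {
            "chrom": 1 + np.arange(m) % 29,
            "pos": 1000 * (1 + np.arange(m)),
            "snp_id": [f"snp{j + 1}" for j in range(m)],
        }
    )
    return GenotypeMatrix(dosage, pedigree.ids.copy(), snp_map)


def simulate_liability_phenotypes(
    pedigree: Pedigree, config: SimulationConfig
) -> GroundTruth:
    """Simulate bivariate breeding values, herd effects and liabilities.

    Breeding values follow the pedigree: founders ~ N(0, Σ_a), offspring =
    parent average + Mendelian-sampling deviation with covariance
    d_i·Σ_a where d_i = ½(1 − (F_s+F_d)/2) for known parents. The liability
    of each cohort animal is intercept + parity effect + HYS effect + a + e,
    and the binary phenotype is 1 exactly when the liability exceeds 0.
    """
    rng = config.rng(3)
    n = len(pedigree)
    r = config.genetic_correlation
    sigma_a = config.true_var_additive * np.array([[1.0, r], [r, 1.0]])
    chol = np.linalg.cholesky(sigma_a + 1e-12 * np.eye(2))

    F = inbreeding(pedigree)
    d = _mendelian_sampling_variance(pedigree, F)
    bv = np.zeros((n, 2))
    ms = rng.standard_normal((n, 2)) @ chol.T
    for i in range(n):
        s, dd = pedigree.sire[i], pedigree.dam[i]
        pa = np.zeros(2)
        if s >= 0:
            pa += 0.5 * bv[s]
        if dd >= 0:
            pa += 0.5 * bv[dd]
        bv[i] = pa + np.sqrt(d[i]) * ms[i]

    cohort = cohort_animals(pedigree)
    nc = cohort.size
    lookup = pedigree.index_of
    cidx = np.array([lookup[a] for a in cohort], dtype=int)

    # herd sizes proportional to a 4-herd study population
    herd_weights = np.array([132.0, 432.0, 1549.0, 239.0])[: config.n_herds]
    herd_weights /= herd_weights.sum()
    herd = rng.choice(config.n_herds, size=nc, p=herd_weights)
    # herd-year-season: seasons nested within herd where levels allow
    per_herd = max(1, config.n_hys_levels // config.n_herds)
    hys = np.minimum(
        herd * per_herd + rng.integers(0, per_herd, size=nc),
        config.n_hys_levels - 1,
    )
    parity = rng.choice([1, 2, 3], size=nc, p=(0.4, 0.3, 0.3))
    parity_eff = np.asarray(config.parity_effects)[parity - 1]

    hys_effects = rng.standard_normal((config.n_hys_levels, 2)) * np.sqrt(
        config.true_var_hys
    )
    resid = rng.standard_normal((nc, 2)) * np.sqrt(config.true_var_residual)

    liab = np.empty((nc, 2))
    for t in range(2):
        liab[:, t] = (
            config.intercept(t)
            + parity_eff
            + hys_effects[hys, t]
            + bv[cidx, t]
            + resid[:, t]
        )
    binary = liab > 0.0

    days = {
        tp: rng.normal(mu, sd, size=nc) for tp, (mu, sd) in TIMEPOINT_DAYS.items()
    }
    # keep T4 strictly after T3 (interval enters the recovery model in days)
    days["T4"] = np.maximum(days["T4"], days["T3"] + 30.0)

    metadata = pd.DataFrame(
        {
            "animal": cohort,
            "herd": herd,
            "parity": parity,
            "hys": hys,
            **{f"days_{tp}": np.round(days[tp]) for tp in TIMEPOINTS},
        }
    )
    return GroundTruth(
        pedigree=pedigree,
        cohort_ids=cohort,
        breeding_values=bv,
        hys_effects=hys_effects,
        liabilities=liab,
        binary_phenotypes=binary,
        metadata=metadata,
        inbreeding=F,
    )


def _unaffected_grade(rng) -> int:
    return int(LesionGrade.MILD_SH) if rng.random() < 0.35 else int(LesionGrade.NONE)


def _affected_grade(rng) -> int:
    p_severe = SEVERITY_RATIO[0] / sum(SEVERITY_RATIO)
    return int(LesionGrade.SEVERE_SH) if rng.random() < p_severe else int(LesionGrade.ULCER)


def simulate_lesion_records(
    truth: GroundTruth, config: SimulationConfig
) -> CohortRecords:
    """Generate claw-level lesion grades and mobility scores from the truth.

    Susceptible animals carry their lesions at T3 (1-4 affected claws,
    severity drawn at the severe-hemorrhage : ulcer ratio observed in early
    lactation); at T4 all affected claws have healed for recovered animals
    while at least one remains affected for chronic animals. Unaffected
    claws are graded none/mild. Records are dropped completely at random at
    ``missing_record_rate``.
    """
    rng = config.rng(4)
    claw_rows = []
    assess_rows = []
    n_claw_probs = np.asarray(N_CLAWS_AFFECTED_PROBS)
    meta = truth.metadata.set_index("animal")

    for ci, animal in enumerate(truth.cohort_ids):
        susceptible = bool(truth.binary_phenotypes[ci, 0])
        recovered = bool(truth.binary_phenotypes[ci, 1])
        row = meta.loc[animal]

        grades = {
            (tp,) + pos: _unaffected_grade(rng)
            for tp in TIMEPOINTS
            for pos in CLAW_POSITIONS
        }
        affected_positions = []
        if susceptible:
            k = 1 + int(rng.choice(4, p=n_claw_probs))
            picks = rng.choice(len(CLAW_POSITIONS), size=k, replace=False)
            affected_positions = [CLAW_POSITIONS[j] for j in picks]
            for pos in affected_positions:
                grades[("T3",) + pos] = _affected_grade(rng)
            if recovered:
                for pos in affected_positions:
                    grades[("T4",) + pos] = _unaffected_grade(rng)
            else:
                chronic = {affected_positions[int(rng.integers(len(affected_positions)))]}
                for pos in affected_positions:
                    if pos in chronic or rng.random() < 0.4:
                        grades[("T4",) + pos] = _affected_grade(rng)
                    else:
                        grades[("T4",) + pos] = _unaffected_grade(rng)

        for tp in TIMEPOINTS:
            affected_now = tp == "T3" and susceptible
            if tp == "T4" and susceptible and not recovered:
                affected_now = True
            p_lame = 0.22 if affected_now else 0.05
            if rng.random() < p_lame:
                mobility = 2 if rng.random() < 0.8 else 3
            else:
                mobility = 0 if rng.random() < 0.75 else 1
            assess_rows.append(
                (
                    animal,
                    tp,
                    float(row[f"days_{tp}"]),
                    mobility,
                    int(row["herd"]),
                    int(row["parity"]),
                    int(row["hys"]),
                )
            )
            for pos in CLAW_POSITIONS:
                if (
                    config.hind_only_t2_herd is not None
                    and tp == "T2"
                    and int(row["herd"]) == config.hind_only_t2_herd
                    and pos[0] == "fore"
                ):
                    continue
                g: float = float(grades[(tp,) + pos])
                if config.missing_record_rate > 0 and rng.random() < config.missing_record_rate:
                    g = np.nan
                claw_rows.append((animal, tp, pos[0], pos[1], pos[2], g))

    claws = pd.DataFrame(
        claw_rows, columns=["animal", "timepoint", "limb", "side", "claw", "grade"]
    )
    assessments = pd.DataFrame(
        assess_rows,
        columns=["animal", "timepoint", "days_from_calving", "mobility", "herd", "parity", "hys"],
    )
    return CohortRecords(claws, assessments)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run the full generator: pedigree → genotypes → truth → records.

    ``genotyped_fraction`` < 1 restricts genotypes to a random cohort
    subset (genotyping panels rarely cover whole pedigrees).
    """
    pedigree = simulate_pedigree(config)
    genotypes = simulate_genotypes(pedigree, config)
    truth = simulate_liability_phenotypes(pedigree, config)
    if config.genotyped_fraction < 1.0:
        rng = config.rng(5)
        n_keep = max(2, int(round(config.genotyped_fraction * truth.cohort_ids.size)))
        chosen = rng.choice(truth.cohort_ids, size=n_keep, replace=False)
        mask = np.isin(genotypes.animal_ids, chosen)
        genotypes = genotypes.subset(animal_mask=mask)
    else:
        mask = np.isin(genotypes.animal_ids, truth.cohort_ids)
        genotypes = genotypes.subset(animal_mask=mask)
    records = simulate_lesion_records(truth, config)
    return SimulatedCohort(config, pedigree, genotypes, truth, records)
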