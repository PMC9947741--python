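"""Synthetic cohort generator: structure, genetics, and round-trips."""

import numpy as np
import pandas as pd
import pytest

from solegen.kinship import inbreeding
from solegen.lesions import derive_traits
from solegen.simulate import (
    ConfigurationError,
    SimulationConfig,
    cohort_animals,
    simulate_cohort,
    simulate_genotypes,
    simulate_liability_phenotypes,
    simulate_pedigree,
)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"true_var_additive": -0.1},
        {"missing_record_rate": 1.5},
        {"n_hys_levels": 0},
        {"founder_maf_range": (0.0, 0.5)},
        {"founder_maf_range": (0.1, 0.6)},
        {"daughters_per_sire_range": (5, 2)},
        {"parity_effects": (0.0, 0.1)},
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        SimulationConfig(**kwargs)


class TestPedigree:
    def test_zero_generations_founders_only(self):
        ped = simulate_pedigree(SimulationConfig(n_founders=25, n_generations=0))
        assert len(ped) == 25
        assert (ped.sire == -1).all() and (ped.dam == -1).all()

    def test_sire_progeny_mean_matches_study_structure(self):
        """Sires average ~5 daughters each, as in the source population."""
        cfg = SimulationConfig(n_founders=2500, daughters_per_sire_range=(2, 8), seed=1)
        ped = simulate_pedigree(cfg)
        sires, counts = np.unique(ped.sire[ped.sire >= 0], return_counts=True)
        assert counts.mean() == pytest.approx(5.0, abs=0.35)
        assert sires.size > 400  # many sires, few daughters each

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_founders=60, seed=9)
        p1, p2 = simulate_pedigree(cfg), simulate_pedigree(cfg)
        assert np.array_equal(p1.ids, p2.ids)
        assert np.array_equal(p1.sire, p2.sire) and np.array_equal(p1.dam, p2.dam)


class TestGenotypes:
    def test_hardy_weinberg_at_half(self):
        cfg = SimulationConfig(
            n_founders=4000, n_generations=0, n_snps=30,
            founder_maf_range=(0.5, 0.5), seed=2,
        )
        ped = simulate_pedigree(cfg)
        G = simulate_genotypes(ped, cfg)
        freqs = [(G.dosages == k).mean() for k in (0, 1, 2)]
        assert freqs[0] == pytest.approx(0.25, abs=0.02)
        assert freqs[1] == pytest.approx(0.50, abs=0.02)
        assert freqs[2] == pytest.approx(0.25, abs=0.02)

    def test_mendelian_transmission_homozygous_parents(self):
        cfg = SimulationConfig(n_founders=40, n_snps=20, seed=3)
        ped = simulate_pedigree(cfg)
        G = simulate_genotypes(ped, cfg)
        both_known = np.flatnonzero((ped.sire >= 0) & (ped.dam >= 0))
        checked = 0
        for i in both_known:
            s, d = ped.sire[i], ped.dam[i]
            ref = (G.dosages[s] == 0) & (G.dosages[d] == 0)
            assert (G.dosages[i][ref] == 0).all()
            alt = (G.dosages[s] == 2) & (G.dosages[d] == 2)
            assert (G.dosages[i][alt] == 2).all()
            checked += int(ref.sum() + alt.sum())
        assert checked > 0

    def test_allele_frequency_drift_within_binomial_envelope(self):
        """Per-SNP cohort frequency stays near the founder frequency.

        Oracle: transmission is neutral, so the cohort frequency is a
        martingale; with n cohort animals the spread around the founder
        frequency is below a 5-sigma binomial envelope at 2n draws.
        """
        cfg = SimulationConfig(n_founders=1500, n_snps=60, seed=4)
        ped = simulate_pedigree(cfg)
        G = simulate_genotypes(ped, cfg)
        founders = (ped.sire == -1) & (ped.dam == -1)
        cohort = ~founders
        f_founder = G.dosages[founders].mean(axis=0) / 2
        f_cohort = G.dosages[cohort].mean(axis=0) / 2
        n = int(cohort.sum())
        envelope = 5 * np.sqrt(f_founder * (1 - f_founder) / (2 * n)) + 0.02
        assert (np.abs(f_cohort - f_founder) < envelope).all()

    def test_missingness_rate_applied(self):
        cfg = SimulationConfig(n_founders=300, n_snps=100, missing_genotype_rate=0.1, seed=5)
        ped = simulate_pedigree(cfg)
        G = simulate_genotypes(ped, cfg)
        assert np.isnan(G.dosages).mean() == pytest.approx(0.1, abs=0.01)


class TestLiabilities:
    def test_symmetric_threshold_gives_half_prevalence(self):
        cfg = SimulationConfig(
            n_founders=4000, n_generations=0, n_snps=2,
            true_var_additive=0.0, true_var_hys=0.0, parity_effects=(0, 0, 0),
            intercept_susceptibility=0.0, intercept_recovery=0.0, seed=6,
        )
        ped = simulate_pedigree(cfg)
        truth = simulate_liability_phenotypes(ped, cfg)
        assert truth.binary_phenotypes[:, 0].mean() == pytest.approx(0.5, abs=0.03)

    def test_default_components_give_h2_quarter(self):
        cfg = SimulationConfig()
        assert cfg.true_var_additive == 0.42
        assert cfg.true_h2 == pytest.approx(0.2456, abs=1e-4)

    def test_prevalence_calibration(self):
        """Inverse-normal intercepts hit the target marginal prevalences."""
        cfg = SimulationConfig(n_founders=2000, n_snps=2, seed=7)
        ped = simulate_pedigree(cfg)
        truth = simulate_liability_phenotypes(ped, cfg)
        prev = truth.binary_phenotypes.mean(axis=0)
        # binomial MC error at n=2000 is ~0.011; hys effects add herd-level noise
        assert prev[0] == pytest.approx(0.44, abs=0.06)
        assert prev[1] == pytest.approx(0.71, abs=0.06)

    def test_founder_breeding_value_variance(self):
        cfg = SimulationConfig(n_founders=3000, n_generations=0, n_snps=2, seed=8)
        ped = simulate_pedigree(cfg)
        truth = simulate_liability_phenotypes(ped, cfg)
        bv = truth.breeding_values
        assert bv[:, 0].var() == pytest.approx(0.42, rel=0.1)
        corr = np.corrcoef(bv[:, 0], bv[:, 1])[0, 1]
        assert corr == pytest.approx(cfg.genetic_correlation, abs=0.06)

    def test_binary_equals_liability_sign(self, small_cohort):
        truth = small_cohort.truth
        assert np.array_equal(truth.binary_phenotypes, truth.liabilities > 0)

    def test_offspring_bv_variance_respects_inbreeding(self):
        """var(MS) = 0.5(1 - (F_s+F_d)/2) sigma2_a, checked via regression."""
        cfg = SimulationConfig(n_founders=3000, n_snps=2, seed=9)
        ped = simulate_pedigree(cfg)
        truth = simulate_liability_phenotypes(ped, cfg)
        bv = truth.breeding_values[:, 0]
        both = np.flatnonzero((ped.sire >= 0) & (ped.dam >= 0))
        ms = bv[both] - 0.5 * (bv[ped.sire[both]] + bv[ped.dam[both]])
        # founders are non-inbred here, so var(MS) = sigma2_a / 2
        assert ms.var() == pytest.approx(0.21, rel=0.1)
        assert abs(ms.mean()) < 0.05


class TestRecordsRoundTrip:
    def test_zero_missingness_recovers_both_traits(self, small_cohort):
        truth = small_cohort.truth
        table = derive_traits(small_cohort.records)
        susc = table[table.trait == "SL-Susceptibility"].set_index("animal")["value"]
        want = pd.Series(
            truth.binary_phenotypes[:, 0].astype(float), index=truth.cohort_ids
        )
        assert (susc.loc[want.index] == want).all()

        rec = table[table.trait == "SL-Recovery"].set_index("animal")["value"]
        affected = want[want == 1].index
        want_rec = pd.Series(
            truth.binary_phenotypes[:, 1].astype(float), index=truth.cohort_ids
        )
        assert (rec.loc[affected] == want_rec.loc[affected]).all()
        assert rec.loc[want[want == 0].index].isna().all()

    def test_missing_claw_at_t4_unclassifies_recovery(self, small_cohort):
        records = small_cohort.records
        truth = small_cohort.truth
        affected = truth.cohort_ids[truth.binary_phenotypes[:, 0]]
        victim = affected[0]
        claws = records.claws.copy()
        mask = (
            (claws.animal == victim) & (claws.timepoint == "T4")
            & (claws.limb == "fore") & (claws.side == "left") & (claws.claw == "medial")
        )
        claws.loc[mask, "grade"] = np.nan
        from solegen.lesions import CohortRecords, classify_recovery

        damaged = CohortRecords(claws, records.assessments)
        assert classify_recovery(damaged, victim).value is None

    def test_missingness_only_unclassifies(self):
        cfg = SimulationConfig(n_founders=120, n_snps=4, missing_record_rate=0.05, seed=10)
        cohort = simulate_cohort(cfg)
        table = derive_traits(cohort.records)
        truth = cohort.truth
        susc = table[table.trait == "SL-Susceptibility"].set_index("animal")["value"]
        want = pd.Series(
            truth.binary_phenotypes[:, 0].astype(float), index=truth.cohort_ids
        )
        classified = susc.dropna()
        assert (classified == want.loc[classified.index]).all()

    def test_bit_identical_under_seed(self):
        cfg = SimulationConfig(n_founders=50, n_snps=20, seed=11)
        c1, c2 = simulate_cohort(cfg), simulate_cohort(cfg)
        assert np.array_equal(c1.genotypes.dosages, c2.genotypes.dosages, equal_nan=True)
        pd.testing.assert_frame_equal(c1.records.claws, c2.records.claws)
        assert np.array_equal(c1.truth.liabilities, c2.truth.liabilities)

    def test_hind_only_herd_flag(self):
        cfg = SimulationConfig(n_founders=200, n_snps=4, hind_only_t2_herd=2, seed=12)
        cohort = simulate_cohort(cfg)
        claws = cohort.records.claws
        meta = cohort.truth.metadata.set_index("animal")
        herd2 = meta[meta.herd == 2].index
        t2 = claws[(claws.timepoint == "T2") & claws.animal.isin(herd2)]
        assert (t2.limb == "hind").all()
        assert len(t2) > 0


def test_cohort_animals_are_last_generation(small_cohort):
    ped = small_cohort.pedigree
    cohort = cohort_animals(ped)
    assert set(cohort) == set(small_cohort.truth.cohort_ids)
    lookup = ped.index_of
    idx = [lookup[a] for a in cohort]
    assert (ped.dam[idx] >= 0).all()
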