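"""Threshold-model construction, Gibbs sampling, and posterior summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from solegen.gibbs import (
    Chain,
    ChainConfig,
    DegeneratePhenotypeError,
    build_model,
    diagnostics,
    gibbs_run,
    hdi,
    heritability,
)
from solegen.kinship import build_relationships
from solegen.lesions import derive_traits
from solegen.simulate import SimulationConfig, simulate_cohort, simulate_pedigree, simulate_liability_phenotypes


def make_chain(variances, a=None, **kw):
    variances = np.asarray(variances, dtype=float)
    m = variances.shape[0]
    a = np.zeros((m, 1)) if a is None else np.asarray(a, dtype=float)
    return Chain(
        trait="SL-Susceptibility",
        config=ChainConfig(length=max(m, 1), burn_in=0, thin=1),
        fixed_names=["intercept"],
        b=np.zeros((m, 1)),
        hys=np.zeros((m, 1)),
        a=a,
        variances=variances,
        animal_ids=np.arange(a.shape[1]) + 1,
        **kw,
    )


class TestChainConfig:
    def test_study_scale_bookkeeping(self):
        cfg = ChainConfig(length=500_000, burn_in=50_000, thin=100)
        assert cfg.n_retained == 4500

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            ChainConfig(length=100, burn_in=100)
        with pytest.raises(ValueError):
            ChainConfig(thin=0)


@pytest.fixture(scope="module")
def fitted_setup():
    cfg = SimulationConfig(
        n_founders=250, n_snps=40, genotyped_fraction=0.4,
        daughters_per_sire_range=(4, 6), seed=21,
    )
    cohort = simulate_cohort(cfg)
    rs = build_relationships(cohort.pedigree, cohort.genotypes)
    traits = derive_traits(cohort.records)
    return cfg, cohort, rs, traits


class TestBuildModel:
    def test_susceptibility_has_no_interval_covariate(self, fitted_setup):
        _, cohort, rs, traits = fitted_setup
        model = build_model(traits, cohort.records.assessments, rs, "SL-Susceptibility")
        assert "interval_t3_t4" not in model.fixed_names
        assert model.fixed_names[:3] == ["intercept", "parity2", "parity3"]

    def test_recovery_includes_centred_interval(self, fitted_setup):
        _, cohort, rs, traits = fitted_setup
        model = build_model(traits, cohort.records.assessments, rs, "SL-Recovery")
        assert model.fixed_names[-1] == "interval_t3_t4"
        interval = model.X[:, -1]
        assert abs(interval.mean()) < 1e-9  # centred
        assert interval.std() > 0

    def test_hys_levels_counted_from_metadata(self, fitted_setup):
        _, cohort, rs, traits = fitted_setup
        model = build_model(traits, cohort.records.assessments, rs, "SL-Susceptibility")
        sub = traits[(traits.trait == "SL-Susceptibility") & traits.value.notna()]
        meta = cohort.records.assessments.drop_duplicates("animal").set_index("animal")
        expected = meta.loc[sub.animal, "hys"].nunique()
        assert model.n_hys == expected

    def test_single_class_is_degenerate(self, fitted_setup):
        _, cohort, rs, traits = fitted_setup
        allsusc = traits.copy()
        allsusc.loc[allsusc.trait == "SL-Susceptibility", "value"] = 1.0
        with pytest.raises(DegeneratePhenotypeError):
            build_model(allsusc, cohort.records.assessments, rs, "SL-Susceptibility")


class TestGibbsRun:
    def test_retained_count_matches_bookkeeping(self, fitted_setup):
        _, cohort, rs, traits = fitted_setup
        model = build_model(traits, cohort.records.assessments, rs, "SL-Susceptibility")
        config = ChainConfig(length=1000, burn_in=100, thin=10, seed=4)
        chain = gibbs_run(model, config)
        assert chain.n_retained == config.n_retained == 90
        assert chain.a.shape == (90, rs.h_inv.shape[0])

    def test_deterministic_under_seed(self, fitted_setup):
        _, cohort, rs, traits = fitted_setup
        model = build_model(traits, cohort.records.assessments, rs, "SL-Susceptibility")
        config = ChainConfig(length=600, burn_in=100, thin=5, seed=7)
        c1 = gibbs_run(model, config)
        c2 = gibbs_run(model, config)
        assert np.array_equal(c1.variances, c2.variances)
        assert np.array_equal(c1.a, c2.a)

    def test_liability_signs_match_phenotypes(self, fitted_setup):
        _, cohort, rs, traits = fitted_setup
        model = build_model(traits, cohort.records.assessments, rs, "SL-Susceptibility")
        chain = gibbs_run(model, ChainConfig(length=500, burn_in=100, thin=5, seed=8))
        lam = chain.final_liabilities
        assert ((lam > 0) == (model.y == 1)).all()

    def test_residual_fixed_at_one_by_default(self, fitted_setup):
        _, cohort, rs, traits = fitted_setup
        model = build_model(traits, cohort.records.assessments, rs, "SL-Susceptibility")
        chain = gibbs_run(model, ChainConfig(length=400, burn_in=100, thin=5, seed=9))
        assert (chain.sigma2_e == 1.0).all()
        chain2 = gibbs_run(
            model,
            ChainConfig(length=400, burn_in=100, thin=5, seed=9, estimate_residual=True),
        )
        assert chain2.sigma2_e.std() > 0

    def test_intercept_approaches_probit_of_prevalence(self):
        """With genetic and HYS variances pinned near zero by a strong prior,
        the model collapses to an intercept-only probit."""
        cfg = SimulationConfig(
            n_founders=1500, n_generations=0, n_snps=2,
            true_var_additive=0.0, true_var_hys=0.0, true_var_residual=1.0,
            parity_effects=(0.0, 0.0, 0.0),
            intercept_susceptibility=sps.norm.ppf(0.3),
            intercept_recovery=0.0, seed=31,
        )
        ped = simulate_pedigree(cfg)
        truth = simulate_liability_phenotypes(ped, cfg)
        traits = pd.DataFrame(
            {
                "animal": truth.cohort_ids,
                "trait": "SL-Susceptibility",
                "value": truth.binary_phenotypes[:, 0].astype(float),
                "interval_days": np.nan,
            }
        )
        rs = build_relationships(ped)
        model = build_model(traits, truth.metadata, rs, "SL-Susceptibility")
        chain = gibbs_run(
            model,
            ChainConfig(length=3000, burn_in=1000, thin=4, seed=5,
                        prior_nu=1e6, prior_scale=1e-9,
                        start_var_hys=1e-3, start_var_a=1e-3),
        )
        prevalence = model.y.mean()
        assert chain.b[:, 0].mean() == pytest.approx(sps.norm.ppf(prevalence), abs=0.12)
        assert chain.sigma2_a.mean() < 1e-2

    def test_recovery_trait_fits(self, fitted_setup):
        _, cohort, rs, traits = fitted_setup
        model = build_model(traits, cohort.records.assessments, rs, "SL-Recovery")
        chain = gibbs_run(model, ChainConfig(length=400, burn_in=100, thin=5, seed=10))
        assert chain.n_retained == 60
        assert np.isfinite(chain.h2).all()
        assert ((chain.h2 > 0) & (chain.h2 < 1)).all()


class TestHeritability:
    def test_posterior_mean_component_ratio(self):
        chain = make_chain([[0.25, 0.42, 1.04]])
        assert heritability(chain)["mean"] == pytest.approx(0.24561403, abs=1e-6)

    def test_zero_additive_sample_gives_zero(self):
        chain = make_chain([[0.25, 0.0, 1.04], [0.25, 0.42, 1.04]])
        assert chain.h2[0] == 0.0

    def test_empty_chain_rejected(self):
        chain = make_chain(np.zeros((0, 3)))
        with pytest.raises(ValueError):
            heritability(chain)


class TestHdi:
    def test_matches_brute_force_shortest_interval(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.gamma(2.0, 1.0, size=40))
        lo, hi = hdi(x, prob=0.9)
        # oracle: exhaustive scan over windows of sorted samples holding at
        # least 90% of the draws (floor(p*n)+1 points)
        m = int(np.floor(0.9 * 40)) + 1
        widths = [
            (x[i + m - 1] - x[i], x[i], x[i + m - 1]) for i in range(40 - m + 1)
        ]
        best = min(widths)
        assert (lo, hi) == pytest.approx((best[1], best[2]))

    def test_hand_made_samples(self):
        # clustered low values with one outlier: the short interval stays low
        x = np.array([0.0, 0.05, 0.1, 0.12, 0.15, 0.2, 0.22, 0.25, 0.3, 5.0])
        lo, hi = hdi(x, prob=0.8)
        assert lo == pytest.approx(0.0) and hi == pytest.approx(0.3)


class TestDiagnostics:
    def test_white_noise_ess_near_n(self):
        rng = np.random.default_rng(1)
        m = 4000
        chain = make_chain(
            np.column_stack([rng.standard_normal(m) + 5,
                             rng.standard_normal(m) + 5,
                             np.ones(m)])
        )
        d = diagnostics(chain)
        assert d.loc["sigma2_hys", "ess"] == pytest.approx(m, rel=0.25)
        assert abs(d.loc["sigma2_hys", "lag1_autocorr"]) < 0.06

    def test_ar1_ess_closed_form(self):
        rng = np.random.default_rng(2)
        m, rho = 6000, 0.6
        x = np.empty(m)
        x[0] = rng.standard_normal()
        for t in range(1, m):
            x[t] = rho * x[t - 1] + rng.standard_normal() * np.sqrt(1 - rho**2)
        chain = make_chain(np.column_stack([x + 5, x + 5, np.ones(m)]))
        d = diagnostics(chain)
        expected = m * (1 - rho) / (1 + rho)  # = m/4
        assert d.loc["sigma2_a", "ess"] == pytest.approx(expected, rel=0.4)
        assert d.loc["sigma2_a", "lag1_autocorr"] == pytest.approx(rho, abs=0.06)

    def test_constant_chain_flagged(self):
        chain = make_chain(np.tile([0.25, 0.42, 1.04], (50, 1)))
        d = diagnostics(chain)
        assert bool(d.loc["sigma2_a", "zero_variance"])
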