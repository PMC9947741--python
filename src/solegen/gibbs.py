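"""Bayesian threshold animal model fitted by Gibbs sampling.

The observed binary phenotype y_i is modelled through a latent liability

    λ = X b + Z_hys hys + Z_a a + e,      y_i = 1 ⇔ λ_i > 0,

with fixed effects b (intercept, parity, and for the recovery trait the
centred T3→T4 interval in days), random herd-year-season effects
hys ~ N(0, I σ²hys), additive genetic effects a ~ N(0, H σ²a) where H is
the combined pedigree-genomic relationship matrix, and residuals
e ~ N(0, I σ²e). The threshold is fixed at 0; by default σ²e is fixed at 1
for identifiability, with an estimate-residual mode available.

Sampling scheme (single-site Gauss–Seidel updates, one numba kernel):

1. each liability from its truncated-normal full conditional (sign
   matching y, inverse-CDF draw);
2. each location effect from its scalar normal full conditional given the
   mixed-model equations at the current variances — for animal effects the
   prior cross-term is a sparse row product with H⁻¹;
3. variances from scaled inverse chi-squared full conditionals
   (weakly-informative proper priors by default — a flat prior makes the
   binary-threshold posterior improper), followed by an interweaved
   rescaling (ASIS) move that decorrelates σ²a from the genetic effects.

Liability-scale heritability is h² = σ²a / (σ²a + σ²hys + σ²e) per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import arviz as az
import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

from .kinship import RelationshipSet

__all__ = [
    "ChainConfig",
    "ModelSpec",
    "Chain",
    "build_model",
    "gibbs_run",
    "heritability",
    "hdi",
    "diagnostics",
]


class DegeneratePhenotypeError(ValueError):
    """The trait has a single observed class; the threshold is unidentifiable."""


@dataclass(frozen=True)
class ChainConfig:
    """Gibbs chain bookkeeping: total length, burn-in, thinning, seed."""

    length: int = 500_000
    burn_in: int = 50_000
    thin: int = 100
    seed: int = 0
    estimate_residual: bool = False
    # scaled inverse chi-squared priors (nu, S) for the variance components.
    # The weakly-informative proper default (prior mean nuS/(nu-2) = 1 on the
    # liability scale, infinite prior variance) is deliberate: with a flat
    # prior (nu=-2, S=0) the joint posterior of a binary threshold model is
    # improper and the variance chain diverges.
    prior_nu: float = 4.0
    prior_scale: float = 0.5
    start_var_hys: float = 0.1
    start_var_a: float = 0.3
    start_var_e: float = 1.0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.length):
            raise ValueError("need 0 <= burn_in < length")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        """Retained posterior draws: (length − burn-in) / thin."""
        return (self.length - self.burn_in) // self.thin


@dataclass
class ModelSpec:
    """Assembled design for one trait's threshold animal model."""

    trait: str
    y: np.ndarray
    X: np.ndarray
    fixed_names: list
    hys_idx: np.ndarray
    n_hys: int
    animal_idx: np.ndarray
    K: sparse.csr_matrix  # relationship inverse (H⁻¹ or A⁻¹), q x q
    animal_ids: np.ndarray  # labels for the q relationship positions

    def __post_init__(self):
        n = self.y.size
        if self.X.shape[0] != n or self.hys_idx.size != n or self.animal_idx.size != n:
            raise ValueError("design matrices not conformable with phenotypes")
        if self.animal_idx.max(initial=-1) >= self.K.shape[0]:
            raise ValueError("phenotyped animal outside the relationship structure")


@dataclass
class Chain:
    """Retained Gibbs samples for one trait."""

    trait: str
    config: ChainConfig
    fixed_names: list
    b: np.ndarray  # (m, p)
    hys: np.ndarray  # (m, n_hys)
    a: np.ndarray  # (m, q)
    variances: np.ndarray  # (m, 3): sigma2_hys, sigma2_a, sigma2_e
    animal_ids: np.ndarray = field(default_factory=lambda: np.array([]))
    final_liabilities: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_retained(self) -> int:
        return self.variances.shape[0]

    @property
    def sigma2_hys(self) -> np.ndarray:
        return self.variances[:, 0]

    @property
    def sigma2_a(self) -> np.ndarray:
        return self.variances[:, 1]

    @property
    def sigma2_e(self) -> np.ndarray:
        return self.variances[:, 2]

    @property
    def h2(self) -> np.ndarray:
        """Per-sample liability-scale heritability."""
        return self.sigma2_a / (self.sigma2_a + self.sigma2_hys + self.sigma2_e)

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "sigma2_hys": self.sigma2_hys,
            "sigma2_a": self.sigma2_a,
            "sigma2_e": self.sigma2_e,
            "h2": self.h2,
        }
        for j, name in enumerate(self.fixed_names):
            cols[f"b_{name}"] = self.b[:, j]
        return pd.DataFrame(cols)


def build_model(
    traits: pd.DataFrame,
    metadata: pd.DataFrame,
    relationships: RelationshipSet,
    trait: str,
) -> ModelSpec:
    """Assemble the threshold-model design for one trait.

    ``traits`` is the long per-animal trait table (animal, trait, value,
    interval_days); unclassified animals are excluded from the likelihood
    but remain in the relationship structure. ``metadata`` needs one row
    per animal with columns animal, parity, hys. The interval covariate
    (centred at its mean) enters the design for SL-Recovery only.
    """
    sub = traits[(traits["trait"] == trait) & traits["value"].notna()]
    if sub.empty:
        raise DegeneratePhenotypeError(f"no classified animals for {trait!r}")
    sub = sub.drop_duplicates("animal")
    y = sub["value"].to_numpy(dtype=np.int8)
    if len(np.unique(y)) < 2:
        raise DegeneratePhenotypeError(
            f"{trait!r} has a single observed class; threshold model unidentifiable"
        )

    meta = metadata.drop_duplicates("animal").set_index("animal")
    try:
        parity = meta.loc[sub["animal"], "parity"].to_numpy()
        hys_raw = meta.loc[sub["animal"], "hys"].to_numpy()
    except KeyError as e:
        raise KeyError(f"phenotyped animal missing from metadata: {e}") from None

    cols = [np.ones(y.size)]
    names = ["intercept"]
    for level in (2, 3):  # first parity class absorbed into the intercept
        cols.append((parity == level).astype(float))
        names.append(f"parity{level}")
    if trait == "SL-Recovery":
        interval = sub["interval_days"].to_numpy(dtype=float)
        if np.isnan(interval).any():
            raise ValueError("interval_days missing for a classified recovery animal")
        cols.append(interval - interval.mean())
        names.append("interval_t3_t4")
    X = np.column_stack(cols)

    hys_levels, hys_idx = np.unique(hys_raw, return_inverse=True)
    lookup = relationships.pedigree.index_of
    try:
        animal_idx = np.array([lookup[a] for a in sub["animal"]], dtype=np.int64)
    except KeyError as e:
        raise KeyError(f"phenotyped animal {e.args[0]!r} not in pedigree") from None

    return ModelSpec(
        trait=trait,
        y=y,
        X=X,
        fixed_names=names,
        hys_idx=hys_idx.astype(np.int64),
        n_hys=hys_levels.size,
        animal_idx=animal_idx,
        K=sparse.csr_matrix(relationships.h_inv),
        animal_ids=relationships.pedigree.ids,
    )


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _probit(p):  # pragma: no cover - numba
    """Inverse standard-normal CDF, Wichura's AS241 (PPND16) approximation."""
    q = p - 0.5
    if abs(q) <= 0.425:
        r = 0.180625 - q * q
        num = (((((((2.5090809287301226727e3 * r + 3.3430575583588128105e4) * r
                    + 6.7265770927008700853e4) * r + 4.5921953931549871457e4) * r
                  + 1.3731693765509461125e4) * r + 1.9715909503065514427e3) * r
                + 1.3314166789178437745e2) * r + 3.3871328727963666080e0)
        den = (((((((5.2264952788528545610e3 * r + 2.8729085735721942674e4) * r
                    + 3.9307895800092710610e4) * r + 2.1213794301586595867e4) * r
                  + 5.3941960214247511077e3) * r + 6.8718700749205790830e2) * r
                + 4.2313330701600911252e1) * r + 1.0)
        return q * num / den
    if q < 0.0:
        r = p
    else:
        r = 1.0 - p
    if r <= 0.0:
        return -np.inf if q < 0.0 else np.inf
    r = np.sqrt(-np.log(r))
    if r <= 5.0:
        r = r - 1.6
        num = (((((((7.74545014278341407640e-4 * r + 2.27238449892691845833e-2) * r
                    + 2.41780725177450611770e-1) * r + 1.27045825245236838258e0) * r
                  + 3.64784832476320460504e0) * r + 5.76949722146069140550e0) * r
                + 4.63033784615654529590e0) * r + 1.42343711074968357734e0)
        den = (((((((1.05075007164441684324e-9 * r + 5.47593808499534494600e-4) * r
                    + 1.51986665636164571966e-2) * r + 1.48103976427480074590e-1) * r
                  + 6.89767334985100004550e-1) * r + 1.67638483018380384940e0) * r
                + 2.05319162663775882187e0) * r + 1.0)
    else:
        r = r - 5.0
        num = (((((((2.01033439929228813265e-7 * r + 2.71155556874348757815e-5) * r
                    + 1.24266094738807843860e-3) * r + 2.65321895265761230930e-2) * r
                  + 2.96560571828504891230e-1) * r + 1.78482653991729133580e0) * r
                + 5.46378491116411436990e0) * r + 6.65790464350110377720e0)
        den = (((((((2.04426310338993978564e-15 * r + 1.42151175831644588870e-7) * r
                    + 1.84631831751005468180e-5) * r + 7.86869131145613259100e-4) * r
                  + 1.48753612908506148525e-2) * r + 1.36929880922735805310e-1) * r
                + 5.99832206555887937690e-1) * r + 1.0)
    val = num / den
    return -val if q < 0.0 else val


@njit(cache=True)
def _trunc_normal(mu, sd, positive):  # pragma: no cover - numba
    """Inverse-CDF draw from N(mu, sd²) truncated to λ>0 or λ<0."""
    u = np.random.random()
    alpha = -mu / sd  # standardized threshold
    if positive:
        tail = 0.5 * math.erfc(alpha / np.sqrt(2.0))  # P(Z > alpha)
        p = u * tail
        if p <= 0.0:
            p = 1e-300
        z = -_probit(p)
    else:
        low = 0.5 * math.erfc(-alpha / np.sqrt(2.0))  # P(Z < alpha)
        p = u * low
        if p <= 0.0:
            p = 1e-300
        z = _probit(p)
    return mu + sd * z


@njit(cache=True)
def _gibbs_kernel(  # pragma: no cover - numba
    y,
    X,
    hys_idx,
    n_hys,
    anim_idx,
    K_indptr,
    K_indices,
    K_data,
    q,
    length,
    burn_in,
    thin,
    seed,
    estimate_residual,
    nu,
    S,
    s2hys0,
    s2a0,
    s2e0,
):
    np.random.seed(seed)
    n = y.size
    p = X.shape[1]

    lam = np.empty(n)
    b = np.zeros(p)
    hys = np.zeros(n_hys)
    a = np.zeros(q)
    s2hys, s2a, s2e = s2hys0, s2a0, s2e0

    # record index per relationship position (-1 = no phenotype)
    rec_of = np.full(q, -1, dtype=np.int64)
    for i in range(n):
        rec_of[anim_idx[i]] = i

    xx = np.empty(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += X[i, j] * X[i, j]
        xx[j] = acc

    hys_counts = np.zeros(n_hys)
    for i in range(n):
        hys_counts[hys_idx[i]] += 1.0

    # residuals e = lam - Xb - hys - a; init lam at +-0.5
    e = np.empty(n)
    for i in range(n):
        lam[i] = 0.5 if y[i] == 1 else -0.5
        e[i] = lam[i]

    n_ret = (length - burn_in) // thin
    out_b = np.empty((n_ret, p))
    out_hys = np.empty((n_ret, n_hys))
    out_a = np.empty((n_ret, q))
    out_var = np.empty((n_ret, 3))

    kept = 0
    hys_sums = np.zeros(n_hys)
    for it in range(length):
        sde = np.sqrt(s2e)

        # (i) liabilities
        for i in range(n):
            mu = lam[i] - e[i]  # current linear predictor
            new = _trunc_normal(mu, sde, y[i] == 1)
            e[i] = new - mu
            lam[i] = new

        # (ii) fixed effects, flat prior
        for j in range(p):
            r = 0.0
            for i in range(n):
                r += X[i, j] * (e[i] + X[i, j] * b[j])
            mean = r / xx[j]
            newb = mean + np.random.standard_normal() * np.sqrt(s2e / xx[j])
            diff = newb - b[j]
            for i in range(n):
                e[i] -= X[i, j] * diff
            b[j] = newb

        # (iii) herd-year-season effects (diagonal block)
        for k in range(n_hys):
            hys_sums[k] = 0.0
        for i in range(n):
            hys_sums[hys_idx[i]] += e[i] + hys[hys_idx[i]]
        for k in range(n_hys):
            prec = hys_counts[k] / s2e + 1.0 / s2hys
            mean = (hys_sums[k] / s2e) / prec
            newh = mean + np.random.standard_normal() / np.sqrt(prec)
            hys_sums[k] = newh - hys[k]  # reuse as diff
            hys[k] = newh
        for i in range(n):
            e[i] -= hys_sums[hys_idx[i]]

        # (iv) additive genetic effects
        for j in range(q):
            kjj = 0.0
            cross = 0.0
            for ptr in range(K_indptr[j], K_indptr[j + 1]):
                col = K_indices[ptr]
                if col == j:
                    kjj += K_data[ptr]
                else:
                    cross += K_data[ptr] * a[col]
            prec = kjj / s2a
            r = -cross / s2a
            rec = rec_of[j]
            if rec >= 0:
                prec += 1.0 / s2e
                r += (e[rec] + a[j]) / s2e
            mean = r / prec
            newa = mean + np.random.standard_normal() / np.sqrt(prec)
            if rec >= 0:
                e[rec] -= newa - a[j]
            a[j] = newa

        # (v) variances from scaled inverse chi-squared full conditionals
        ss_h = 0.0
        for k in range(n_hys):
            ss_h += hys[k] * hys[k]
        df_h = n_hys + nu
        s2hys = (ss_h + nu * S) / np.random.chisquare(df_h)

        aKa = 0.0
        for j in range(q):
            for ptr in range(K_indptr[j], K_indptr[j + 1]):
                aKa += a[j] * K_data[ptr] * a[K_indices[ptr]]
        df_a = q + nu
        s2a = (aKa + nu * S) / np.random.chisquare(df_a)

        if estimate_residual:
            ss_e = 0.0
            for i in range(n):
                ss_e += e[i] * e[i]
            s2e = (ss_e + nu * S) / np.random.chisquare(n + nu)
        else:
            s2e = 1.0

        # (vi) interweaved rescaling move for the genetic scale (ASIS):
        # with the whitened effects a~ = a/sigma_a held fixed, sigma_a acts
        # as a regression coefficient on a~ in the liability model, so a
        # direct draw from that regression conditional (MH-corrected for
        # the flat variance prior) decorrelates sigma2_a from a.
        s_cur = np.sqrt(s2a)
        denom = 0.0
        num = 0.0
        for i in range(n):
            at = a[anim_idx[i]] / s_cur
            r_full = e[i] + a[anim_idx[i]]
            denom += at * at
            num += at * r_full
        if denom > 0.0:
            vprop = s2e / denom
            mprop = num / denom
            s_new = mprop + np.random.standard_normal() * np.sqrt(vprop)
            # independence-MH correction: target ∝ lik(s)·p(s²)·|s|,
            # proposal ∝ lik(s); p is the scaled-inv-chi2 variance prior
            accept = False
            if abs(s_new) > 0.0:
                v_new = s_new * s_new
                log_ratio = (
                    -(nu / 2.0 + 1.0) * (np.log(v_new) - np.log(s2a))
                    - 0.5 * nu * S * (1.0 / v_new - 1.0 / s2a)
                    + np.log(abs(s_new)) - np.log(s_cur)
                )
                accept = np.log(np.random.random()) < log_ratio
            if accept:
                scale = s_new / s_cur
                for j in range(q):
                    a[j] *= scale
                for i in range(n):
                    e[i] = (e[i] + a[anim_idx[i]] / scale) - a[anim_idx[i]]
                s2a = s_new * s_new

        if not (np.isfinite(s2hys) and np.isfinite(s2a) and np.isfinite(s2e)):
            return out_b, out_hys, out_a, out_var, lam, it

        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_ret:
            for j in range(p):
                out_b[kept, j] = b[j]
            for k in range(n_hys):
                out_hys[kept, k] = hys[k]
            for j in range(q):
                out_a[kept, j] = a[j]
            out_var[kept, 0] = s2hys
            out_var[kept, 1] = s2a
            out_var[kept, 2] = s2e
            kept += 1

    return out_b, out_hys, out_a, out_var, lam, -1


def gibbs_run(model: ModelSpec, config: ChainConfig) -> Chain:
    """Run the Gibbs sampler and return the retained chain.

    Fully reproducible from ``config.seed``. Raises ``FloatingPointError``
    with the failing iteration if a variance draw becomes non-finite.
    """
    K = model.K
    out_b, out_hys, out_a, out_var, final_lam, failed_at = _gibbs_kernel(
        model.y.astype(np.int8),
        np.ascontiguousarray(model.X, dtype=np.float64),
        model.hys_idx,
        model.n_hys,
        model.animal_idx,
        K.indptr,
        K.indices,
        K.data,
        K.shape[0],
        config.length,
        config.burn_in,
        config.thin,
        config.seed,
        config.estimate_residual,
        config.prior_nu,
        config.prior_scale,
        config.start_var_hys,
        config.start_var_a,
        config.start_var_e,
    )
    if failed_at >= 0:
        raise FloatingPointError(
            f"non-finite variance draw at iteration {failed_at}"
        )
    return Chain(
        trait=model.trait,
        config=config,
        fixed_names=model.fixed_names,
        b=out_b,
        hys=out_hys,
        a=out_a,
        variances=out_var,
        animal_ids=model.animal_ids,
        final_liabilities=final_lam,
    )


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------


def hdi(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` posterior mass (via arviz)."""
    lo, hi = az.hdi(np.asarray(samples, dtype=float), hdi_prob=prob)
    return float(lo), float(hi)


def heritability(chain: Chain, prob: float = 0.95) -> dict:
    """Posterior summary of liability-scale h² = σ²a/(σ²a+σ²hys+σ²e)."""
    if chain.n_retained == 0:
        raise ValueError("empty chain")
    h2 = chain.h2
    lo, hi = hdi(h2, prob) if h2.size > 1 else (float(h2[0]), float(h2[0]))
    return {
        "mean": float(h2.mean()),
        "hdi_low": lo,
        "hdi_high": hi,
        "prob": prob,
        "n_samples": int(h2.size),
    }


def diagnostics(chain: Chain) -> pd.DataFrame:
    """Convergence diagnostics per variance parameter (and h²).

    Columns: effective sample size, lag-1 autocorrelation, split-chain
    stationarity z-score (first vs second half of the retained chain), and
    a zero-variance flag for degenerate chains.
    """
    if chain.n_retained < 2:
        raise ValueError("need at least 2 retained samples")
    rows = {}
    series = {
        "sigma2_hys": chain.sigma2_hys,
        "sigma2_a": chain.sigma2_a,
        "sigma2_e": chain.sigma2_e,
        "h2": chain.h2,
    }
    for name, x in series.items():
        x = np.asarray(x, dtype=float)
        v = x.var(ddof=1)
        if v <= 1e-20 * (1.0 + abs(x.mean())) ** 2:
            rows[name] = {"ess": np.nan, "lag1_autocorr": np.nan,
                          "split_z": np.nan, "zero_variance": True}
            continue
        ess = float(az.ess(x))
        xc = x - x.mean()
        lag1 = float(np.dot(xc[:-1], xc[1:]) / np.dot(xc, xc))
        half = x.size // 2
        a, bb = x[:half], x[half:]
        z = (a.mean() - bb.mean()) / np.sqrt(
            a.var(ddof=1) / a.size + bb.var(ddof=1) / bb.size
        )
        rows[name] = {"ess": ess, "lag1_autocorr": lag1,
                      "split_z": float(z), "zero_variance": False}
    return pd.DataFrame(rows).T
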