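"""Breeding values, reliabilities, and the approximate genetic correlation.

GEBV are posterior means of the additive effects from a threshold-model
chain; PEV is the posterior variance of each animal's additive effect
("squared standard error of the GEBV"); reliability is

    REL_i = 1 − PEV_i / ((1 + F_i) σ²a),

with F_i the pedigree inbreeding coefficient and σ²a the posterior-mean
additive variance from the same chain. The genetic correlation between two
traits is approximated from the correlation between their GEBV in the
subset of animals with both phenotypes, inflated for the imperfect
reliabilities (Calo et al. adjustment):

    r̃ = r × √(ΣREL₁ · ΣREL₂) / Σ√(REL₁ · REL₂),
    SE(r̃) = √((1 − r̃²)/(n − 2)),   CI95 = r̃ ± 1.96·SE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gibbs import Chain

__all__ = [
    "CorrelationEstimate",
    "gebv_from_chain",
    "calo_correlation",
    "correlation_interval",
]


def correlation_interval(r_adj: float, n: int, level_z: float = 1.96) -> tuple[float, float, float]:
    """SE and normal CI for an approximate genetic correlation.

    SE = sqrt((1 - r̃²)/(n - 2)); returns (se, ci_low, ci_high).
    """
    if n <= 2:
        raise ValueError("need n > 2")
    se = float(np.sqrt((1.0 - r_adj**2) / (n - 2)))
    return se, float(r_adj - level_z * se), float(r_adj + level_z * se)


@dataclass
class CorrelationEstimate:
    r_gebv: float
    r_adjusted: float
    adjustment_factor: float
    n: int
    se: float
    ci_low: float
    ci_high: float


def gebv_from_chain(chain: Chain, pedigree_F: np.ndarray) -> pd.DataFrame:
    """Per-animal GEBV table (animal, gebv, pev, rel, F) from a chain.

    ``pedigree_F`` must align with ``chain.animal_ids`` (one inbreeding
    coefficient per relationship position). Reliabilities outside [0, 1]
    are clipped with a warning.
    """
    pedigree_F = np.asarray(pedigree_F, dtype=float)
    q = chain.a.shape[1]
    if pedigree_F.size != q:
        raise KeyError(
            f"inbreeding coefficients ({pedigree_F.size}) do not match the "
            f"{q} animals in the additive-effect chain"
        )
    gebv = chain.a.mean(axis=0)
    pev = chain.a.var(axis=0, ddof=1) if chain.n_retained > 1 else np.zeros(q)
    sigma2_a = float(chain.sigma2_a.mean())
    rel = 1.0 - pev / ((1.0 + pedigree_F) * sigma2_a)
    n_clip = int(((rel < 0.0) | (rel > 1.0)).sum())
    if n_clip:
        warnings.warn(f"clipped {n_clip} reliabilities to [0, 1]", stacklevel=2)
    rel = np.clip(rel, 0.0, 1.0)
    return pd.DataFrame(
        {
            "animal": chain.animal_ids,
            "gebv": gebv,
            "pev": pev,
            "rel": rel,
            "F": pedigree_F,
        }
    )


def calo_correlation(
    t1: pd.DataFrame,
    t2: pd.DataFrame,
    subset: np.ndarray,
    level_z: float = 1.96,
    literal: bool = False,
) -> CorrelationEstimate:
    """Reliability-adjusted correlation between two traits' GEBV.

    ``subset`` lists the animals with both phenotypes recorded. With all
    reliabilities equal to 1 the adjustment factor is exactly 1
    (Cauchy-Schwarz equality) and r̃ = r. ``literal=True`` applies the
    adjustment without square roots — an n-scaled audit variant that does
    not return a correlation-scale value.
    """
    subset = np.asarray(subset)
    if subset.size <= 2:
        raise ValueError("need more than 2 animals with both phenotypes")
    a = t1.set_index("animal").loc[subset]
    b = t2.set_index("animal").loc[subset]
    g1, g2 = a["gebv"].to_numpy(), b["gebv"].to_numpy()
    if g1.std() == 0.0 or g2.std() == 0.0:
        raise ZeroDivisionError("zero GEBV variance; correlation undefined")
    r = float(np.corrcoef(g1, g2)[0, 1])
    rel1, rel2 = a["rel"].to_numpy(), b["rel"].to_numpy()
    if literal:
        factor = rel1.sum() * rel2.sum() / np.sum(rel1 * rel2)
    else:
        factor = np.sqrt(rel1.sum() * rel2.sum()) / np.sum(np.sqrt(rel1 * rel2))
    r_adj = r * factor
    if abs(r_adj) > 1.0:
        warnings.warn(
            f"adjusted correlation {r_adj:.3f} overshoots; truncated to +-1",
            stacklevel=2,
        )
        r_adj = float(np.clip(r_adj, -1.0, 1.0))
    n = int(subset.size)
    se, lo, hi = correlation_interval(r_adj, n, level_z)
    return CorrelationEstimate(
        r_gebv=r,
        r_adjusted=float(r_adj),
        adjustment_factor=float(factor),
        n=n,
        se=se,
        ci_low=lo,
        ci_high=hi,
    )
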