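"""Pedigree and genomic relationship machinery for single-step evaluation.

Builds the numerator relationship matrix A (tabular method), pedigree
inbreeding coefficients F (Meuwissen & Luo recursion), the sparse inverse
A⁻¹ (Henderson's rules accounting for inbreeding), the genomic relationship
matrix G (VanRaden's first method), and the combined single-step inverse

    H⁻¹ = A⁻¹ + [0  0; 0  (G*)⁻¹ − A22⁻¹]

on the genotyped block, where G* is G tuned to the scale of the pedigree
block A22 and blended with it for invertibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

from .qc import GenotypeMatrix

__all__ = [
    "Pedigree",
    "RelationshipSet",
    "inbreeding",
    "a_matrix",
    "a_inverse",
    "g_matrix",
    "h_inverse",
    "build_relationships",
]

UNKNOWN = -1


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically ordered pedigree: parents precede offspring.

    ``ids`` are the external animal labels; ``sire`` and ``dam`` are
    positional indices into ``ids`` (-1 = unknown parent).
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = self.ids.size
        if self.sire.size != n or self.dam.size != n:
            raise PedigreeError("id/sire/dam arrays must have equal length")
        for parents in (self.sire, self.dam):
            bad = (parents >= np.arange(n)) & (parents != UNKNOWN)
            if bad.any():
                raise PedigreeError(
                    "pedigree is not topologically ordered (a parent does not "
                    "precede its offspring); use Pedigree.from_frame"
                )

    def __len__(self) -> int:
        return self.ids.size

    @property
    def index_of(self) -> dict:
        return {a: i for i, a in enumerate(self.ids)}

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from columns animal/sire/dam; 0, blank or NaN = unknown.

        Rows are re-sorted topologically (Kahn's algorithm); a cycle —
        an animal that is its own ancestor — raises ``PedigreeError``.
        """

        def norm(v):
            if pd.isna(v) or v == 0 or v == "" or v == "0":
                return None
            return v

        animals = [norm(a) for a in frame["animal"]]
        if any(a is None for a in animals):
            raise PedigreeError("animal id may not be missing/0")
        if len(set(animals)) != len(animals):
            raise PedigreeError("duplicate animal ids in pedigree")
        sires = [norm(s) for s in frame["sire"]]
        dams = [norm(d) for d in frame["dam"]]
        known = set(animals)
        # parents referenced but never listed become founders
        extras = [
            p for p in dict.fromkeys(sires + dams) if p is not None and p not in known
        ]
        all_ids = extras + animals
        parent_map = {a: (s, d) for a, s, d in zip(animals, sires, dams)}

        children: dict = {a: [] for a in all_ids}
        indeg = {a: 0 for a in all_ids}
        for a in all_ids:
            s, d = parent_map.get(a, (None, None))
            for p in (s, d):
                if p is not None:
                    children[p].append(a)
                    indeg[a] += 1
        order = [a for a in all_ids if indeg[a] == 0]
        head = 0
        while head < len(order):
            for c in children[order[head]]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
            head += 1
        if len(order) != len(all_ids):
            raise PedigreeError("pedigree contains a cycle")
        pos = {a: i for i, a in enumerate(order)}
        sire_idx = np.full(len(order), UNKNOWN, dtype=np.int64)
        dam_idx = np.full(len(order), UNKNOWN, dtype=np.int64)
        for a in order:
            s, d = parent_map.get(a, (None, None))
            if s is not None:
                sire_idx[pos[a]] = pos[s]
            if d is not None:
                dam_idx[pos[a]] = pos[d]
        return cls(np.asarray(order), sire_idx, dam_idx)

    def to_frame(self) -> pd.DataFrame:
        def lab(idx):
            return np.where(idx == UNKNOWN, 0, np.take(self.ids, np.maximum(idx, 0)))

        return pd.DataFrame(
            {"animal": self.ids, "sire": lab(self.sire), "dam": lab(self.dam)}
        )


@njit(cache=True)
def _inbreeding_ml(sire, dam):  # pragma: no cover - exercised via inbreeding()
    n = sire.size
    F = np.zeros(n)
    D = np.empty(n)
    L = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0:
            D[i] = 0.75 - 0.25 * F[s]
        elif d >= 0:
            D[i] = 0.75 - 0.25 * F[d]
        else:
            D[i] = 1.0
        if s < 0 or d < 0:
            continue  # F stays 0: an unknown parent is unrelated by assumption
        L[i] = 1.0
        aii = 0.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj != 0.0:
                aii += lj * lj * D[j]
                if sire[j] >= 0:
                    L[sire[j]] += 0.5 * lj
                if dam[j] >= 0:
                    L[dam[j]] += 0.5 * lj
                L[j] = 0.0
        F[i] = aii - 1.0
    return F


def inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Exact pedigree inbreeding coefficients via the Meuwissen–Luo recursion.

    F_i = A_ii − 1 with A_ii accumulated from the Cholesky-style L·D
    decomposition of A traced over the ancestors of each animal. Founders
    and animals with an unknown parent have F = 0.
    """
    return _inbreeding_ml(pedigree.sire, pedigree.dam)


def _mendelian_sampling_variance(pedigree: Pedigree, F: np.ndarray) -> np.ndarray:
    """Within-family (Mendelian sampling) variance coefficients d_i."""
    d = np.ones(len(pedigree))
    s, m = pedigree.sire, pedigree.dam
    both = (s >= 0) & (m >= 0)
    d[both] = 0.5 - 0.25 * (F[s[both]] + F[m[both]])
    one_s = (s >= 0) & (m < 0)
    d[one_s] = 0.75 - 0.25 * F[s[one_s]]
    one_m = (s < 0) & (m >= 0)
    d[one_m] = 0.75 - 0.25 * F[m[one_m]]
    return d


@njit(cache=True)
def _a_tabular(sire, dam):  # pragma: no cover
    n = sire.size
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            aij = 0.0
            if s >= 0:
                aij += 0.5 * A[j, s]
            if d >= 0:
                aij += 0.5 * A[j, d]
            A[i, j] = aij
            A[j, i] = aij
    return A


def a_matrix(
    pedigree: Pedigree,
    subset=None,
    subset_is_index: bool = False,
    max_dense: int = 10000,
) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    ``subset`` restricts the returned rows and columns — animal ids by
    default, positional indices if ``subset_is_index``. The recursion
    always runs over the full pedigree.
    """
    if len(pedigree) > max_dense:
        raise MemoryError(
            f"pedigree of {len(pedigree)} animals exceeds max_dense={max_dense}"
        )
    A = _a_tabular(pedigree.sire, pedigree.dam)
    if subset is None:
        return A
    if subset_is_index:
        idx = np.asarray(subset, dtype=np.int64)
    else:
        lookup = pedigree.index_of
        try:
            idx = np.array([lookup[a] for a in np.asarray(subset).tolist()], dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"animal {e.args[0]!r} not in pedigree") from None
    return A[np.ix_(idx, idx)]


def a_inverse(pedigree: Pedigree, F: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse A⁻¹ by Henderson's rules with inbreeding.

    Each animal contributes α = 1/d_i (d_i the Mendelian sampling variance
    coefficient from parental inbreeding) to the (animal, sire, dam) block.
    Agrees with the dense inverse of the tabular A to numerical precision.
    """
    if F is None:
        F = inbreeding(pedigree)
    d = _mendelian_sampling_variance(pedigree, F)
    alpha = 1.0 / d
    n = len(pedigree)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        a = alpha[i]
        s, m = pedigree.sire[i], pedigree.dam[i]
        add(i, i, a)
        for p in (s, m):
            if p >= 0:
                add(i, p, -a / 2.0)
                add(p, i, -a / 2.0)
        for p in (s, m):
            if p >= 0:
                add(p, p, a / 4.0)
        if s >= 0 and m >= 0:
            add(s, m, a / 4.0)
            add(m, s, a / 4.0)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n, n), dtype=float
    )


def g_matrix(G: GenotypeMatrix, freqs: np.ndarray | None = None) -> np.ndarray:
    """VanRaden (method 1) genomic relationship matrix.

    Missing dosages are imputed to the SNP mean; dosages are centred by
    twice the allele frequency (observed in the genotyped set unless
    ``freqs`` is supplied) and the cross-product scaled by 2Σp(1−p).
    """
    if G.n_animals < 2:
        raise ValueError("need at least 2 genotyped animals")
    M = G.dosages.copy()
    if freqs is None:
        freqs = G.allele_frequencies()
    poly = (freqs > 0.0) & (freqs < 1.0)
    if not poly.any():
        raise ValueError("all SNPs monomorphic; G undefined")
    M = M[:, poly]
    p = freqs[poly]
    col_mean = 2.0 * p
    nan_mask = np.isnan(M)
    if nan_mask.any():
        M[nan_mask] = np.broadcast_to(col_mean, M.shape)[nan_mask]
    Z = M - col_mean
    denom = 2.0 * np.sum(p * (1.0 - p))
    return Z @ Z.T / denom


def _tune_to_a22(Gm: np.ndarray, A22: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Rescale G so its mean diagonal/off-diagonal match A22: G_t = a + b·G."""
    n = Gm.shape[0]
    off = ~np.eye(n, dtype=bool)
    gd, go = Gm.diagonal().mean(), Gm[off].mean() if n > 1 else 0.0
    ad, ao = A22.diagonal().mean(), A22[off].mean() if n > 1 else 0.0
    denom = gd - go
    if abs(denom) < 1e-12:
        return Gm.copy(), 0.0, 1.0
    b = (ad - ao) / denom
    a = ad - b * gd
    return a + b * Gm, a, b


def h_inverse(
    a_inv: sparse.spmatrix,
    Gm: np.ndarray,
    A22: np.ndarray,
    genotyped_idx: np.ndarray,
    blend_alpha: float = 0.95,
    tune: bool = True,
) -> sparse.csr_matrix:
    """Single-step combined relationship inverse H⁻¹.

    G is optionally tuned (mean diagonal and off-diagonal matched to A22),
    then blended, G* = α·G_t + (1−α)·A22, and the genotyped block of A⁻¹ is
    corrected by (G*)⁻¹ − A22⁻¹. With no genotyped animals H⁻¹ = A⁻¹.
    """
    genotyped_idx = np.asarray(genotyped_idx, dtype=np.int64)
    if genotyped_idx.size == 0:
        return sparse.csr_matrix(a_inv)
    if not 0.0 < blend_alpha <= 1.0:
        raise ValueError("blend_alpha must be in (0, 1]")
    Gt = _tune_to_a22(Gm, A22)[0] if tune else Gm
    G_star = blend_alpha * Gt + (1.0 - blend_alpha) * A22
    try:
        G_star_inv = np.linalg.inv(G_star)
        A22_inv = np.linalg.inv(A22)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"singular blended genomic block ({e}); decrease blend_alpha"
        ) from e
    delta = G_star_inv - A22_inv
    delta = 0.5 * (delta + delta.T)
    ii = np.repeat(genotyped_idx, genotyped_idx.size)
    jj = np.tile(genotyped_idx, genotyped_idx.size)
    H_inv = sparse.csr_matrix(a_inv, copy=True) + sparse.csr_matrix(
        (delta.ravel(), (ii, jj)), shape=a_inv.shape
    )
    return H_inv.tocsr()


@dataclass
class RelationshipSet:
    """All relationship structures needed for a single-step threshold fit."""

    pedigree: Pedigree
    F: np.ndarray
    a_inv: sparse.csr_matrix
    h_inv: sparse.csr_matrix
    genotyped_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    G: np.ndarray | None = None
    A22: np.ndarray | None = None


def build_relationships(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix | None = None,
    blend_alpha: float = 0.95,
    tune: bool = True,
) -> RelationshipSet:
    """Assemble F, A⁻¹ and (when genotypes are given) G, A22 and H⁻¹.

    Genotyped animals absent from the pedigree raise ``KeyError``. Without
    genotypes the combined inverse degenerates to A⁻¹.
    """
    F = inbreeding(pedigree)
    a_inv = a_inverse(pedigree, F)
    if genotypes is None or genotypes.n_animals == 0:
        return RelationshipSet(pedigree, F, a_inv, a_inv.copy())
    lookup = pedigree.index_of
    try:
        gidx = np.array([lookup[a] for a in genotypes.animal_ids], dtype=np.int64)
    except KeyError as e:
        raise KeyError(f"genotyped animal {e.args[0]!r} not in pedigree") from None
    Gm = g_matrix(genotypes)
    A22 = a_matrix(pedigree, subset=gidx, subset_is_index=True)
    h_inv = h_inverse(a_inv, Gm, A22, gidx, blend_alpha=blend_alpha, tune=tune)
    return RelationshipSet(pedigree, F, a_inv, h_inv, gidx, Gm, A22)
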