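"""Ploidy-independent population differentiation (Rho) and Mantel tests.

Rho measures among-site differentiation purely through *between*-individual
gene identity: with Q2 the mean probability that two alleles drawn from two
different individuals of the same site are identical, and Q3 the same
probability for individuals of different sites,

    Rho = (Q2 - Q3) / (1 - Q3).

Because within-individual identity never enters, Rho is insensitive to
ploidy and to the (unknown) number of allele copies per individual -- the
property that makes it usable for multilocus presence/absence genotypes and
comparable across marker systems (e.g. against a diploid microsatellite
panel).  Pairwise values are linearised as Rho/(1 - Rho) for
isolation-by-distance analyses via Mantel and partial Mantel tests.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DiploidPanel:
    """Codominant diploid genotypes: individual -> locus -> (allele, allele).

    Missing genotypes are stored as ``None`` (a cell holds exactly 0 or 2
    allele labels).
    """

    loci: list[str]
    site_of: dict[str, str]
    genotypes: dict[str, dict[str, tuple[str, str] | None]]
    sites: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sites:
            seen: list[str] = []
            for ind in self.genotypes:
                s = self.site_of[ind]
                if s not in seen:
                    seen.append(s)
            self.sites = seen

    def individuals(self, site: str | None = None) -> list[str]:
        if site is None:
            return list(self.genotypes)
        return [i for i in self.genotypes if self.site_of[i] == site]


@dataclass
class DifferentiationMatrix:
    """Pairwise Rho with its Rho/(1-Rho) transform and permutation p-values."""

    sites: list[str]
    rho: pd.DataFrame
    rho_transformed: pd.DataFrame
    p_values: pd.DataFrame | None
    global_rho: float
    global_transformed: float
    n_perm: int
    marker_label: str = ""


def transform_rho(rho: float) -> float:
    """Rho/(1 - Rho); +inf at the Rho = 1 boundary."""
    return math.inf if rho >= 1.0 else rho / (1.0 - rho)


# ---------------------------------------------------------------------------
# gene identity


def identity_between_individuals(g1, g2) -> float:
    """Probability that one allele drawn from each individual matches.

    ``g1``/``g2`` are either presence sets (multilocus MHC genotypes) or
    diploid multi-locus genotypes (``dict locus -> (a, b) | None``), in
    which case the identity is averaged over loci typed in both.
    """
    if isinstance(g1, (set, frozenset)):
        if not g1 or not g2:
            raise ValueError("empty allele set")
        return len(g1 & g2) / (len(g1) * len(g2))
    vals = []
    for locus, pair1 in g1.items():
        pair2 = g2.get(locus)
        if pair1 is None or pair2 is None:
            continue
        matches = sum(a == b for a in pair1 for b in pair2)
        vals.append(matches / 4.0)
    if not vals:
        raise ValueError("no locus typed in both individuals")
    return float(np.mean(vals))


def _genotype_list(data, site: str):
    if isinstance(data, Dataset):
        return [set(g.alleles) for g in data.site_genotypes([site])]
    return [data.genotypes[i] for i in data.individuals(site)]


def _identity_matrix(genos) -> np.ndarray:
    """All-pairs between-individual identity, computed once and reused.

    Gene identity between two individuals does not depend on site labels,
    so permutation tests only re-partition the rows of this matrix.
    """
    n = len(genos)
    if n and isinstance(genos[0], (set, frozenset)):
        alleles = sorted(set().union(*genos))
        idx = {a: j for j, a in enumerate(alleles)}
        X = np.zeros((n, len(alleles)))
        for i, g in enumerate(genos):
            if not g:
                raise ValueError("empty allele set")
            for a in g:
                X[i, idx[a]] = 1.0
        r = X.sum(axis=1)
        return (X @ X.T) / np.outer(r, r)
    loci = sorted({L for g in genos for L in g})
    num = np.zeros((n, n))
    cnt = np.zeros((n, n))
    for L in loci:
        labels = sorted(
            {a for g in genos if g.get(L) for a in g[L]}
        )
        idx = {a: j for j, a in enumerate(labels)}
        W = np.zeros((n, len(labels)))
        typed = np.zeros(n, dtype=bool)
        for i, g in enumerate(genos):
            pair = g.get(L)
            if pair is None:
                continue
            typed[i] = True
            for a in pair:
                W[i, idx[a]] += 0.5
        block = np.outer(typed, typed)
        num += np.where(block, W @ W.T, 0.0)
        cnt += block
    if (cnt == 0).any():
        bad = np.argwhere(cnt == 0)
        raise ValueError(f"no locus typed in both individuals (first pair {bad[0]})")
    return num / cnt


def _block_means(M: np.ndarray, n_r: int) -> tuple[float, float, float]:
    """(within-r mean, within-s mean, between mean) for a 2-site split."""
    n = M.shape[0]
    iu_r = np.triu_indices(n_r, k=1)
    iu_s = np.triu_indices(n - n_r, k=1)
    if not iu_r[0].size or not iu_s[0].size:
        raise ValueError("need >= 2 individuals per site")
    w_r = float(M[:n_r, :n_r][iu_r].mean())
    w_s = float(M[n_r:, n_r:][iu_s].mean())
    between = float(M[:n_r, n_r:].mean())
    return w_r, w_s, between


def _rho_from_blocks(w_r: float, w_s: float, between: float) -> float:
    q2 = (w_r + w_s) / 2.0
    if between >= 1.0:
        raise ValueError("Rho undefined: all individuals identical (Q3 = 1)")
    return (q2 - between) / (1.0 - between)


def rho_pairwise(data: Dataset | DiploidPanel, site_r: str, site_s: str) -> float:
    """Pairwise Rho between two sites.

    Q2 is the average of the two sites' within-site mean identities; Q3 the
    mean identity over all cross-site individual pairs.
    """
    gr, gs = _genotype_list(data, site_r), _genotype_list(data, site_s)
    M = _identity_matrix(gr + gs)
    return _rho_from_blocks(*_block_means(M, len(gr)))


def rho_global(data: Dataset | DiploidPanel) -> tuple[float, float]:
    """Global Rho over all sites and its Rho/(1-Rho) transform.

    Q2 pools all within-site individual pairs with equal weight; Q3 pools
    all cross-site pairs.
    """
    sites = data.sites
    if len(sites) < 2:
        raise ValueError("need >= 2 sites")
    genos = []
    labels = []
    for s in sites:
        for g in _genotype_list(data, s):
            genos.append(g)
            labels.append(s)
    M = _identity_matrix(genos)
    labels = np.array(labels)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(genos), k=1)
    within_mask = same[iu]
    q2 = float(M[iu][within_mask].mean())
    q3 = float(M[iu][~within_mask].mean())
    if q3 >= 1.0:
        raise ValueError("Rho undefined: all individuals identical (Q3 = 1)")
    rho = (q2 - q3) / (1.0 - q3)
    return rho, transform_rho(rho)


def rho_permutation_test(
    data: Dataset | DiploidPanel,
    site_r: str,
    site_s: str,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permute individuals between two sites; upper-tail add-one p for Rho."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    gr, gs = _genotype_list(data, site_r), _genotype_list(data, site_s)
    n_r = len(gr)
    M = _identity_matrix(gr + gs)
    observed = _rho_from_blocks(*_block_means(M, n_r))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(M.shape[0])
        Mp = M[np.ix_(perm, perm)]
        try:
            null = _rho_from_blocks(*_block_means(Mp, n_r))
        except ValueError:
            continue
        if null >= observed - 1e-12:
            exceed += 1
    return observed, (1 + exceed) / (n_perm + 1)


def differentiation_matrix(
    data: Dataset | DiploidPanel,
    n_perm: int = 999,
    seed: int = 0,
    marker_label: str = "",
) -> DifferentiationMatrix:
    """All pairwise Rho (transformed) with permutation p-values."""
    sites = data.sites
    rho = pd.DataFrame(0.0, index=sites, columns=sites)
    pvals = pd.DataFrame(np.nan, index=sites, columns=sites)
    rng = np.random.default_rng(seed)
    for r, s in itertools.combinations(sites, 2):
        value, p = rho_permutation_test(
            data, r, s, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        )
        rho.loc[r, s] = rho.loc[s, r] = value
        pvals.loc[r, s] = pvals.loc[s, r] = p
    g_rho, g_tr = rho_global(data)
    return DifferentiationMatrix(
        sites=list(sites),
        rho=rho,
        rho_transformed=rho.map(transform_rho),
        p_values=pvals,
        global_rho=g_rho,
        global_transformed=g_tr,
        n_perm=n_perm,
        marker_label=marker_label,
    )


# ---------------------------------------------------------------------------
# Mantel tests


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(m, k=1)
    return m[iu]


def _check_square(*mats: np.ndarray) -> list[np.ndarray]:
    out = []
    shape = None
    for m in mats:
        arr = np.asarray(m, dtype=float)
        if isinstance(m, pd.DataFrame):
            arr = m.to_numpy(dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("distance matrices must be square")
        if shape is not None and arr.shape != shape:
            raise ValueError("distance matrices must share one site order")
        shape = arr.shape
        out.append(arr)
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("Mantel r undefined: constant matrix")
    return float(np.corrcoef(x, y)[0, 1])


def mantel(m1, m2, n_perm: int = 719, seed: int = 0) -> tuple[float, float]:
    """Mantel test: Pearson r over upper-triangle entries; one-tailed upper p.

    The null permutes rows and columns of ``m1`` simultaneously; p uses the
    add-one estimator over ``n_perm`` permutations.
    """
    a, b = _check_square(m1, m2)
    r_obs = _pearson(_upper(a), _upper(b))
    rng = np.random.default_rng(seed)
    yb = _upper(b)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(a.shape[0])
        exceed += _pearson(_upper(a[np.ix_(perm, perm)]), yb) >= r_obs - 1e-12
    return r_obs, (1 + exceed) / (n_perm + 1)


def _partial_r(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    r12, r13, r23 = _pearson(x, y), _pearson(x, z), _pearson(y, z)
    denom = math.sqrt((1 - r13**2) * (1 - r23**2))
    if denom == 0:
        raise ValueError("partial Mantel r undefined: covariate collinear")
    return (r12 - r13 * r23) / denom


def partial_mantel(m1, m2, m3, n_perm: int = 719, seed: int = 0) -> tuple[float, float]:
    """Partial Mantel: correlation of ``m1`` and ``m2`` controlling for ``m3``.

    If ``m3`` is constant the statistic reduces to the simple Mantel r.
    The null permutes rows/columns of the raw ``m1`` (residual-based
    permutation); one-tailed upper add-one p.
    """
    a, b, c = _check_square(m1, m2, m3)
    x, y, z = _upper(a), _upper(b), _upper(c)
    if z.std() == 0:
        logger.info("partial Mantel covariate constant; reduces to simple Mantel")
        return mantel(m1, m2, n_perm=n_perm, seed=seed)
    r_obs = _partial_r(x, y, z)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(a.shape[0])
        xp = _upper(a[np.ix_(perm, perm)])
        try:
            exceed += _partial_r(xp, y, z) >= r_obs - 1e-12
        except ValueError:
            continue
    return r_obs, (1 + exceed) / (n_perm + 1)


def geographic_distance(
    coords: dict[str, tuple[float, float]],
    sites: list[str] | None = None,
    lonlat: bool = False,
) -> pd.DataFrame:
    """Site-by-site distance matrix: great-circle (km) if ``lonlat``, else Euclidean.

    ``lonlat`` coordinates are (longitude, latitude) in degrees.
    """
    sites = sites or list(coords)
    missing = [s for s in sites if s not in coords]
    if missing:
        raise KeyError(f"missing coordinates for site(s): {missing}")
    n = len(sites)
    out = np.zeros((n, n))
    for i, r in enumerate(sites):
        for j, s in enumerate(sites):
            if j <= i:
                continue
            x1, y1 = coords[r]
            x2, y2 = coords[s]
            if lonlat:
                lon1, lat1, lon2, lat2 = map(math.radians, (x1, y1, x2, y2))
                h = (
                    math.sin((lat2 - lat1) / 2) ** 2
                    + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
                )
                d = 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))
            else:
                d = math.hypot(x2 - x1, y2 - y1)
            out[i, j] = out[j, i] = d
    logger.info("geographic distances in %s", "km (great-circle)" if lonlat else "coordinate units (Euclidean)")
    return pd.DataFrame(out, index=sites, columns=sites)
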