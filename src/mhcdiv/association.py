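"""Pairwise index of association between alleles in presence/absence data.

For two alleles *a*, *b* scored across *n* individuals, define for every
unordered individual pair (i, j) the mismatch indicators
``d_a(i,j) = 1`` iff i and j differ in presence of *a* (likewise ``d_b``).
The index of association is

    I_A = Var(d_a + d_b) / (Var(d_a) + Var(d_b)) - 1
        = 2 Cov(d_a, d_b) / (Var(d_a) + Var(d_b))

with population (divide-by-N) moments over all n(n-1)/2 pairs.  I_A = 1
signals perfect co-segregation; its null distribution under independent
assortment is obtained by permuting one allele's column across
individuals.  Alleles can co-segregate through physical linkage or
disassortative mating, so significant pairs feed the linked-genotype
null simulator downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset, incidence_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationResult:
    """One tested allele pair (unordered) with its I_A and permutation p."""

    pair: tuple[str, str]
    ia: float
    p_value: float
    n_perm: int
    bonferroni_threshold: float
    significant: bool


def _column(incidence, key) -> np.ndarray:
    if isinstance(incidence, pd.DataFrame):
        col = incidence[key].to_numpy()
    else:
        col = np.asarray(incidence)[:, key]
    return col.astype(np.int64)


def _ia_from_counts(n: int, n11: float, n10: float, n01: float, n00: float) -> float:
    # moments of the pair-mismatch indicators depend only on the 2x2 table
    npairs = n * (n - 1) / 2.0
    ka = n11 + n10
    kb = n11 + n01
    e_da = ka * (n - ka) / npairs
    e_db = kb * (n - kb) / npairs
    var_da = e_da - e_da**2
    var_db = e_db - e_db**2
    e_dadb = (n11 * n00 + n10 * n01) / npairs
    cov = e_dadb - e_da * e_db
    denom = var_da + var_db
    if denom == 0.0:
        raise ValueError("I_A undefined: monomorphic allele column")
    return float(2.0 * cov / denom)


def pairwise_ia(incidence, a, b) -> float:
    """I_A between allele columns ``a`` and ``b`` of an incidence matrix.

    Raises ``ValueError`` when either column is monomorphic (all 0 or
    all 1), for which the index is undefined.
    """
    xa, xb = _column(incidence, a), _column(incidence, b)
    n = len(xa)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if xa.sum() in (0, n) or xb.sum() in (0, n):
        raise ValueError("I_A undefined: monomorphic allele column")
    n11 = int(np.sum(xa & xb))
    n10 = int(np.sum(xa & (1 - xb)))
    n01 = int(np.sum((1 - xa) & xb))
    n00 = n - n11 - n10 - n01
    return _ia_from_counts(n, n11, n10, n01, n00)


def ia_permutation_test(
    incidence, a, b, n_perm: int = 99_999, seed: int = 0
) -> tuple[float, float]:
    """Permutation p-value for I_A(a, b) under independent assortment.

    Column ``b`` is independently permuted across individuals ``n_perm``
    times; the upper-tail p uses the add-one estimator
    ``p = (1 + #{null I_A >= observed}) / (n_perm + 1)``, so p >= 1/(n_perm+1).
    Returns ``(observed I_A, p)``; deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = pairwise_ia(incidence, a, b)
    xa, xb = _column(incidence, a), _column(incidence, b)
    n = len(xa)
    ka, kb = int(xa.sum()), int(xb.sum())
    rng = np.random.default_rng(seed)
    # under a uniform permutation of column b, the carrier overlap
    # |a & perm(b)| is exactly hypergeometric with the columns' margins,
    # and I_A given fixed margins is a function of that overlap alone --
    # so the permutation null is sampled without materialising permutations
    m = rng.hypergeometric(kb, n - kb, ka, size=n_perm)
    npairs = n * (n - 1) / 2.0
    e_da = ka * (n - ka) / npairs
    e_db = kb * (n - kb) / npairs
    var_da = e_da - e_da**2
    var_db = e_db - e_db**2
    n10 = ka - m
    n01 = kb - m
    n00 = n - ka - kb + m
    e_dadb = (m * n00 + n10 * n01) / npairs
    null_ia = 2.0 * (e_dadb - e_da * e_db) / (var_da + var_db)
    exceed = int(np.sum(null_ia >= observed - 1e-12))
    return observed, (1 + exceed) / (n_perm + 1)


def significant_pairs(
    data: Dataset | pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 99_999,
    seed: int = 0,
    site_filter=None,
) -> list[AssociationResult]:
    """Test every unordered polymorphic allele pair; Bonferroni-correct.

    Pairs with a monomorphic member are untestable and excluded from the
    Bonferroni denominator.  A pair is significant iff its permutation p
    is at most ``alpha / n_tested_pairs``.  Results are sorted by p.
    """
    if isinstance(data, Dataset):
        inc = incidence_matrix(data, site_filter=site_filter)
    else:
        inc = data
    n = len(inc)
    counts = inc.sum(axis=0)
    poly = [c for c in inc.columns if 0 < counts[c] < n]
    pairs = [(a, b) for i, a in enumerate(poly) for b in poly[i + 1:]]
    if not pairs:
        logger.warning("no polymorphic allele pairs to test")
        return []
    threshold = alpha / len(pairs)
    rng = np.random.default_rng(seed)
    results = []
    for a, b in pairs:
        ia, p = ia_permutation_test(
            inc, a, b, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        )
        results.append(
            AssociationResult(
                pair=(a, b),
                ia=ia,
                p_value=p,
                n_perm=n_perm,
                bonferroni_threshold=threshold,
                significant=p <= threshold,
            )
        )
    return sorted(results, key=lambda r: (r.p_value, -r.ia))


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabular view (one row per tested pair) for TSV export."""
    return pd.DataFrame(
        [
            {
                "allele_1": r.pair[0],
                "allele_2": r.pair[1],
                "I_A": r.ia,
                "p": r.p_value,
                "n_perm": r.n_perm,
                "bonferroni_threshold": r.bonferroni_threshold,
                "significant": r.significant,
            }
            for r in results
        ]
    )
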