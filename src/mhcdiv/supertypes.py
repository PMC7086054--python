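"""Supertype clustering of MHC alleles from physicochemical descriptors.

Alleles whose antigen-binding residues are biochemically similar bind
overlapping antigen repertoires and are grouped into one functional
"supertype".  Each positively selected site (PSS) of the translated
fragment is replaced by the residue's five z-scale descriptors; alleles
are then k-means-clustered in the resulting 5*|PSS|-dimensional space,
and the number of clusters is chosen from the BIC curve by an explicit
elbow rule (smallest k after which the BIC drop becomes negligible).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .data import AlleleCatalog, MultilocusGenotype
from .zscales import STANDARD_AMINO_ACIDS, z_vector

logger = logging.getLogger(__name__)

#: relative floor for the within-cluster sum of squares inside the BIC log:
#: WSS is floored at this fraction of the total sum of squares, so that
#: degenerate solutions (k at or above the number of distinct descriptor
#: rows, where WSS collapses to 0) score as a deep but finite BIC drop
#: instead of dominating the whole curve's range.
WSS_EPS_FRACTION = 1e-3


@dataclass
class DescriptorEncoding:
    """Alleles x (5*|PSS|) real matrix of concatenated z-descriptors."""

    allele_ids: list[str]
    pss_positions: list[int]
    matrix: np.ndarray

    @property
    def n_alleles(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SupertypeModel:
    """A fitted allele -> supertype assignment with its model-selection trace."""

    k: int
    assignment: dict[str, int]
    bic_curve: dict[int, float]
    seed: int
    n_starts: int
    drop_threshold: float = 0.01

    def __post_init__(self) -> None:
        labels = set(self.assignment.values())
        if labels != set(range(1, self.k + 1)):
            raise ValueError(f"supertype labels must be contiguous 1..{self.k}, got {sorted(labels)}")

    def supertype_of(self, allele_id: str) -> int:
        try:
            return self.assignment[allele_id]
        except KeyError:
            raise KeyError(f"allele {allele_id!r} has no supertype assignment") from None


def encode_pss(catalog: AlleleCatalog, pss_positions: list[int]) -> DescriptorEncoding:
    """Encode each allele's residues at the PSS as concatenated z-descriptors.

    ``pss_positions`` are 1-based amino-acid positions within the translated
    fragment.  Identical residues at every PSS yield identical rows.
    """
    if not pss_positions:
        raise ValueError("no PSS positions given")
    pep_len = catalog.peptide_length
    bad = [p for p in pss_positions if not 1 <= p <= pep_len]
    if bad:
        raise ValueError(f"PSS position(s) {bad} outside peptide length {pep_len}")
    rows = []
    for allele_id, pep in catalog.peptides.items():
        residues = [pep[p - 1] for p in pss_positions]
        nonstd = [r for r in residues if r not in STANDARD_AMINO_ACIDS]
        if nonstd:
            raise ValueError(f"non-standard residue(s) {nonstd} in allele {allele_id!r}")
        rows.append(np.concatenate([z_vector(r) for r in residues]))
    return DescriptorEncoding(
        allele_ids=catalog.allele_ids,
        pss_positions=list(pss_positions),
        matrix=np.vstack(rows),
    )


def kmeans_bic_scan(
    encoding: DescriptorEncoding,
    k_range: range | list[int],
    n_starts: int = 20,
    seed: int = 0,
) -> tuple[dict[int, float], dict[int, np.ndarray]]:
    """Best-of-``n_starts`` k-means for each k, scored by BIC.

    BIC(k) = n * ln(WSS_k / n) + k * ln(n), with n the allele count and
    WSS_k the total within-cluster sum of squares of the best solution.
    WSS is floored at ``WSS_EPS_FRACTION`` of the total sum of squares so
    that duplicate-row degeneracies (WSS = 0) remain scoreable.
    Deterministic given ``seed``.
    """
    ks = sorted(set(int(k) for k in k_range))
    n = encoding.n_alleles
    if not ks:
        raise ValueError("empty k range")
    if ks[0] < 1 or ks[-1] > n:
        raise ValueError(f"k range {ks[0]}..{ks[-1]} outside [1, {n}]")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    bic: dict[int, float] = {}
    labels: dict[int, np.ndarray] = {}
    X = encoding.matrix
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    wss_floor = WSS_EPS_FRACTION * tss if tss > 0 else 1e-12
    for k in ks:
        if k == 1:
            centre = X.mean(axis=0)
            wss = float(((X - centre) ** 2).sum())
            lab = np.zeros(n, dtype=int)
        else:
            with warnings.catch_warnings():
                # k above the number of distinct rows is permitted (WSS -> 0)
                warnings.simplefilter("ignore", ConvergenceWarning)
                km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed).fit(X)
            wss = float(km.inertia_)
            lab = km.labels_
        bic[k] = n * np.log(max(wss, wss_floor) / n) + k * np.log(n)
        labels[k] = lab
    return bic, labels


def choose_k(bic_curve: dict[int, float], drop_threshold: float = 0.01) -> int:
    """Elbow rule: smallest k whose BIC drop to k+1 is negligible.

    "Negligible" means a decrease smaller than ``drop_threshold`` times the
    total range of the curve.  A flat curve returns the smallest k; a
    monotone-increasing curve also returns the smallest k, with a warning.
    """
    ks = sorted(bic_curve)
    if len(ks) < 3:
        raise ValueError("BIC curve must cover at least 3 k values")
    values = np.array([bic_curve[k] for k in ks])
    span = float(values.max() - values.min())
    if span == 0.0:
        return ks[0]
    if np.all(np.diff(values) >= 0):
        logger.warning("BIC curve is monotone increasing; returning smallest k=%d", ks[0])
        return ks[0]
    for i in range(len(ks) - 1):
        drop = values[i] - values[i + 1]
        if drop < drop_threshold * span:
            return ks[i]
    return ks[-1]


def fit_supertypes(
    catalog: AlleleCatalog,
    pss_positions: list[int],
    k_range: range | list[int] | None = None,
    n_starts: int = 20,
    seed: int = 0,
    drop_threshold: float = 0.01,
    k_override: int | None = None,
) -> SupertypeModel:
    """Encode, scan k, choose the elbow, and return the fitted model.

    ``k_override`` forces a cluster number (logged); otherwise
    :func:`choose_k` picks it from the BIC curve.  Cluster labels are
    renumbered 1..k by order of first appearance in catalog order, so the
    assignment is invariant under k-means' internal label permutation.
    """
    encoding = encode_pss(catalog, pss_positions)
    if k_range is None:
        k_range = range(1, min(15, encoding.n_alleles) + 1)
    bic, labels = kmeans_bic_scan(encoding, k_range, n_starts=n_starts, seed=seed)
    if k_override is not None:
        logger.info("supertype count manually overridden to k=%d", k_override)
        k = k_override
        if k not in labels:
            _, extra = kmeans_bic_scan(encoding, [k], n_starts=n_starts, seed=seed)
            labels[k] = extra[k]
    else:
        k = choose_k(bic, drop_threshold=drop_threshold)
    lab = labels[k]
    relabel: dict[int, int] = {}
    for raw in lab:
        if raw not in relabel:
            relabel[raw] = len(relabel) + 1
    assignment = {a: relabel[raw] for a, raw in zip(encoding.allele_ids, lab)}
    return SupertypeModel(
        k=len(relabel),
        assignment=assignment,
        bic_curve=bic,
        seed=seed,
        n_starts=n_starts,
        drop_threshold=drop_threshold,
    )


def count_supertypes(genotype: MultilocusGenotype, model: SupertypeModel) -> int:
    """Number of distinct supertypes among the genotype's alleles."""
    return len({model.supertype_of(a) for a in genotype.alleles})
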