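"""Null-model simulation of multilocus genotypes and supertype-count tests.

To ask whether individuals carry more functionally distinct MHC variants
(supertypes) than expected if alleles assorted at random, observed
per-individual supertype counts are compared against ensembles of
artificial genotypes assembled from the alleles' observed incidence
frequencies.  Two assembly modes bracket the plausible null models:

* ``unlinked`` -- every allele enters a genotype independently with its
  incidence probability (empty draws rejected and redrawn);
* ``linked`` -- Bonferroni-significant allele pairs are additionally
  treated as all-or-none units, emulating complete association.

The observed distribution is compared to the ensemble distribution with a
Kolmogorov-Smirnov statistic appropriate for discrete data (Monte-Carlo
p-value against the fixed discrete null) and with a mean-based empirical
test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import Dataset, MultilocusGenotype, incidence_matrix
from .supertypes import SupertypeModel

logger = logging.getLogger(__name__)

DEFAULT_ENSEMBLE_SIZE = 50_000


@dataclass
class IncidenceSpectrum:
    """Per-allele incidence fractions (share of carriers) in one site group."""

    freq: dict[str, float]
    n_source: int

    def __post_init__(self) -> None:
        bad = {a: f for a, f in self.freq.items() if not 0.0 < f <= 1.0}
        if bad:
            raise ValueError(f"incidence frequencies must lie in (0, 1]: {bad}")


@dataclass
class NullEnsemble:
    """A simulated genotype set stored as a boolean incidence matrix."""

    mode: str
    allele_ids: list[str]
    matrix: np.ndarray  # n_genotypes x n_alleles, bool
    seed: int
    linked_pairs: list[tuple[str, str]] = field(default_factory=list)
    n_rejected: int = 0

    @property
    def n_genotypes(self) -> int:
        return self.matrix.shape[0]

    def supertype_counts(self, model: SupertypeModel) -> np.ndarray:
        """Per-genotype number of distinct supertypes."""
        labels = np.array([model.supertype_of(a) for a in self.allele_ids])
        onehot = np.zeros((len(self.allele_ids), model.k), dtype=bool)
        onehot[np.arange(len(labels)), labels - 1] = True
        return (self.matrix @ onehot).astype(bool).sum(axis=1)

    def count_histogram(self, model: SupertypeModel) -> dict[int, int]:
        vals, counts = np.unique(self.supertype_counts(model), return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def mean_count(self, model: SupertypeModel) -> float:
        return float(self.supertype_counts(model).mean())


@dataclass
class KSComparison:
    """Two-sample-style KS comparison of observed counts vs a fixed null."""

    D: float
    p_value: float
    method: str
    n_resamples: int


def incidence_spectrum(dataset: Dataset, site_group) -> IncidenceSpectrum:
    """Observed incidence fraction of every allele carried in ``site_group``."""
    genotypes = dataset.site_genotypes(site_group)
    if not genotypes:
        raise ValueError("empty site group")
    inc = incidence_matrix(dataset, site_filter=site_group)
    carriers = inc.sum(axis=0)
    freq = {
        a: carriers[a] / len(genotypes) for a in inc.columns if carriers[a] > 0
    }
    return IncidenceSpectrum(freq=freq, n_source=len(genotypes))


def _fill_rejected(matrix: np.ndarray, draw) -> int:
    """Redraw all-zero rows until none remain; return rejection count."""
    rejected = 0
    empty = ~matrix.any(axis=1)
    while empty.any():
        rejected += int(empty.sum())
        matrix[empty] = draw(int(empty.sum()))
        empty = ~matrix.any(axis=1)
    return rejected


def simulate_unlinked(
    spectrum: IncidenceSpectrum,
    n_genotypes: int = DEFAULT_ENSEMBLE_SIZE,
    seed: int = 0,
    assembly: str = "bernoulli",
    count_dist: dict[int, float] | None = None,
) -> NullEnsemble:
    """Assemble genotypes with independently occurring alleles.

    ``assembly='bernoulli'`` (default): each allele enters each genotype
    independently with its incidence probability; all-zero genotypes are
    rejected and redrawn.  ``assembly='fixed_counts'``: the per-genotype
    allele count is drawn from ``count_dist`` and that many distinct
    alleles are sampled with probability proportional to incidence.
    """
    if n_genotypes < 1:
        raise ValueError("n_genotypes must be >= 1")
    alleles = list(spectrum.freq)
    probs = np.array([spectrum.freq[a] for a in alleles])
    rng = np.random.default_rng(seed)
    if assembly == "bernoulli":
        draw = lambda m: rng.random((m, len(alleles))) < probs
        matrix = draw(n_genotypes)
        n_rejected = _fill_rejected(matrix, draw)
        if n_rejected:
            logger.info("rejected and redrew %d empty genotype(s)", n_rejected)
    elif assembly == "fixed_counts":
        if not count_dist:
            raise ValueError("fixed_counts assembly requires count_dist")
        sizes = np.array(sorted(count_dist))
        size_p = np.array([count_dist[s] for s in sizes], dtype=float)
        size_p /= size_p.sum()
        w = probs / probs.sum()
        matrix = np.zeros((n_genotypes, len(alleles)), dtype=bool)
        counts = rng.choice(sizes, size=n_genotypes, p=size_p)
        for i, c in enumerate(counts):
            chosen = rng.choice(len(alleles), size=min(c, len(alleles)), replace=False, p=w)
            matrix[i, chosen] = True
        n_rejected = 0
    else:
        raise ValueError(f"unknown assembly mode {assembly!r}")
    return NullEnsemble(
        mode="unlinked", allele_ids=alleles, matrix=matrix, seed=seed,
        n_rejected=n_rejected,
    )


def simulate_linked(
    spectrum: IncidenceSpectrum,
    linked_pairs: list[tuple[str, str]],
    n_genotypes: int = DEFAULT_ENSEMBLE_SIZE,
    seed: int = 0,
    linkage_mode: str = "complete",
    linkage_strengths: dict[tuple[str, str], float] | None = None,
) -> NullEnsemble:
    """Assemble genotypes with linked allele pairs as all-or-none units.

    Each linked pair is included jointly with probability equal to the mean
    of its members' incidence frequencies (logged per pair); remaining
    alleles assort independently as in :func:`simulate_unlinked`.  Pairs
    must be disjoint.  ``linkage_mode='proportional'`` softens the unit:
    with probability ``linkage_strengths[pair]`` the pair behaves as a
    unit, otherwise the members assort independently.
    """
    seen: set[str] = set()
    for a, b in linked_pairs:
        if a in seen or b in seen or a == b:
            raise ValueError(f"linked pairs must be disjoint; offending pair ({a}, {b})")
        for m in (a, b):
            if m not in spectrum.freq:
                raise ValueError(f"linked-pair member {m!r} absent from spectrum")
            seen.add(m)
    if linkage_mode not in ("complete", "proportional"):
        raise ValueError(f"unknown linkage_mode {linkage_mode!r}")
    alleles = list(spectrum.freq)
    idx = {a: j for j, a in enumerate(alleles)}
    free = np.array([a not in seen for a in alleles])
    probs = np.array([spectrum.freq[a] for a in alleles])
    pair_idx = [(idx[a], idx[b]) for a, b in linked_pairs]
    pair_p = np.array(
        [(spectrum.freq[a] + spectrum.freq[b]) / 2.0 for a, b in linked_pairs]
    )
    for (a, b), p in zip(linked_pairs, pair_p):
        logger.info("linked pair (%s, %s): unit inclusion probability %.4f", a, b, p)
    strengths = np.ones(len(linked_pairs))
    if linkage_mode == "proportional":
        strengths = np.array(
            [(linkage_strengths or {}).get((a, b), 1.0) for a, b in linked_pairs]
        )
    rng = np.random.default_rng(seed)

    def draw(m: int) -> np.ndarray:
        mat = np.zeros((m, len(alleles)), dtype=bool)
        mat[:, free] = rng.random((m, int(free.sum()))) < probs[free]
        for (ja, jb), p_unit, s in zip(pair_idx, pair_p, strengths):
            as_unit = rng.random(m) < s
            unit_in = rng.random(m) < p_unit
            mat[:, ja] |= as_unit & unit_in
            mat[:, jb] |= as_unit & unit_in
            solo = ~as_unit
            if solo.any():
                mat[solo, ja] = rng.random(int(solo.sum())) < probs[ja]
                mat[solo, jb] = rng.random(int(solo.sum())) < probs[jb]
        return mat

    matrix = draw(n_genotypes)
    n_rejected = _fill_rejected(matrix, draw)
    return NullEnsemble(
        mode="linked", allele_ids=alleles, matrix=matrix, seed=seed,
        linked_pairs=list(linked_pairs), n_rejected=n_rejected,
    )


# ---------------------------------------------------------------------------
# discrete Kolmogorov-Smirnov comparison


def _cdf_on(support: np.ndarray, values: np.ndarray, weights=None) -> np.ndarray:
    order = np.argsort(values)
    values = np.asarray(values)[order]
    w = (
        np.full(len(values), 1.0 / len(values))
        if weights is None
        else np.asarray(weights, dtype=float)[order] / np.sum(weights)
    )
    cum = np.cumsum(w)
    return np.concatenate([[0.0], cum])[np.searchsorted(values, support, side="right")]


def discrete_ks_test(
    observed_counts,
    ensemble_or_hist,
    model: SupertypeModel | None = None,
    n_resamples: int = 100_000,
    seed: int = 0,
) -> KSComparison:
    """One-sample KS test of discrete counts against a fixed discrete null.

    The null CDF is the ensemble's empirical distribution of supertype
    counts (or any histogram ``{value: count}``).  D is the sup distance
    between the observed ECDF and the null CDF over the union support; the
    p-value is Monte-Carlo: ``n_resamples`` samples of size n_obs are drawn
    from the null and ``p = (1 + #{D* >= D}) / (n_resamples + 1)``.
    """
    observed = np.asarray(list(observed_counts))
    if observed.size == 0:
        raise ValueError("empty observed sample")
    if isinstance(ensemble_or_hist, NullEnsemble):
        if model is None:
            raise ValueError("a SupertypeModel is required with a NullEnsemble")
        hist = ensemble_or_hist.count_histogram(model)
    else:
        hist = dict(ensemble_or_hist)
    null_vals = np.array(sorted(hist))
    null_w = np.array([hist[v] for v in null_vals], dtype=float)
    null_p = null_w / null_w.sum()
    support = np.union1d(observed, null_vals)
    cdf_null = _cdf_on(support, null_vals, null_w)
    cdf_obs = _cdf_on(support, observed)
    d_obs = float(np.max(np.abs(cdf_obs - cdf_null)))
    if d_obs < 1e-12:  # float noise from cumulative sums; CDFs identical
        d_obs = 0.0

    rng = np.random.default_rng(seed)
    n_obs = observed.size
    # resampled ECDFs jump only on the null support; evaluate there plus the
    # observed support so every jump point of either CDF is covered
    counts = rng.multinomial(n_obs, null_p, size=n_resamples)
    cum = np.cumsum(counts, axis=1) / n_obs
    cum_full = np.zeros((n_resamples, len(support)))
    pos = np.searchsorted(null_vals, support, side="right")
    cum_padded = np.concatenate([np.zeros((n_resamples, 1)), cum], axis=1)
    cum_full = cum_padded[:, pos]
    d_null = np.max(np.abs(cum_full - cdf_null), axis=1)
    p = (1 + int(np.sum(d_null >= d_obs - 1e-12))) / (n_resamples + 1)
    return KSComparison(
        D=d_obs, p_value=p, method="monte-carlo discrete KS", n_resamples=n_resamples
    )


def compare_supertype_means(
    observed_genotypes: list[MultilocusGenotype],
    model: SupertypeModel,
    ensemble: NullEnsemble,
    n_resamples: int = 100_000,
    seed: int = 0,
) -> dict:
    """Observed vs null mean individual supertype count, with KS and mean tests.

    Returns a report dict with both means (2 decimals in the formatted
    fields), full histograms, the KS comparison, and a two-sided empirical
    p for the mean (fraction of same-size null resamples whose mean is at
    least as extreme as observed).
    """
    from .supertypes import count_supertypes

    obs = np.array([count_supertypes(g, model) for g in observed_genotypes])
    null_counts = ensemble.supertype_counts(model)
    ks = discrete_ks_test(
        obs, ensemble.count_histogram(model), n_resamples=n_resamples, seed=seed
    )
    rng = np.random.default_rng(seed + 1)
    null_mean = float(null_counts.mean())
    draws = rng.choice(null_counts, size=(n_resamples, obs.size), replace=True)
    means = draws.mean(axis=1)
    p_mean = (1 + int(np.sum(np.abs(means - null_mean) >= abs(obs.mean() - null_mean) - 1e-12))) / (
        n_resamples + 1
    )
    obs_hist = {int(v): int(c) for v, c in zip(*np.unique(obs, return_counts=True))}
    return {
        "observed_mean": float(obs.mean()),
        "null_mean": null_mean,
        "observed_mean_2dp": round(float(obs.mean()), 2),
        "null_mean_2dp": round(null_mean, 2),
        "observed_histogram": obs_hist,
        "null_histogram": ensemble.count_histogram(model),
        "ks_D": ks.D,
        "ks_p": ks.p_value,
        "mean_p": p_mean,
        "n_observed": int(obs.size),
        "ensemble_size": ensemble.n_genotypes,
        "mode": ensemble.mode,
        "seed": ensemble.seed,
    }
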