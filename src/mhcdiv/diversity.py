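"""Per-site and per-individual diversity statistics for allele catalogs.

Covers the classic summary columns for a multigene-family amplicon survey:
allele counts and private alleles, rarefied allelic richness, segregating
sites, nucleotide diversity (total and partitioned into synonymous /
nonsynonymous components by unweighted Nei-Gojobori codon counting), and
the mean within-individual amino-acid p-distance at positively selected
sites.  All sequence statistics are computed over *unique* alleles,
unweighted by incidence, because allele dosage is unknown in
presence/absence genotypes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .data import AlleleCatalog, Dataset, MultilocusGenotype
from .supertypes import SupertypeModel, count_supertypes

logger = logging.getLogger(__name__)

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_CODON_TABLE.stop_codons)
_NT = "ACGT"


def _aa(codon: str) -> str:
    return _CODON_TABLE.forward_table[codon]


# ---------------------------------------------------------------------------
# allele counts and rarefaction


def allele_counts(dataset: Dataset, site: str) -> tuple[int, int]:
    """(A, A_priv): distinct alleles at ``site`` and those private to it."""
    if site not in dataset.sites:
        raise KeyError(f"unknown site {site!r}")
    here = set().union(*(g.alleles for g in dataset.site_genotypes([site])))
    elsewhere: set[str] = set()
    for g in dataset.genotypes:
        if g.site_id != site:
            elsewhere |= g.alleles
    return len(here), len(here - elsewhere)


def rarefied_richness(dataset: Dataset, site: str, g: int) -> float:
    """Expected allele count in ``g`` individual-allele presence records.

    With N total records at the site (one record per individual-allele
    presence) of which n_a belong to allele a,

        A_R = sum_a [ 1 - C(N - n_a, g) / C(N, g) ].

    At g = N this equals A; at g = 1 it equals 1.
    """
    genotypes = dataset.site_genotypes([site])
    records: dict[str, int] = {}
    for geno in genotypes:
        for a in geno.alleles:
            records[a] = records.get(a, 0) + 1
    n_total = sum(records.values())
    if not 1 <= g <= n_total:
        raise ValueError(f"draw size g={g} outside [1, {n_total}] for site {site!r}")
    denom = math.comb(n_total, g)
    return float(sum(1.0 - math.comb(n_total - n_a, g) / denom for n_a in records.values()))


# ---------------------------------------------------------------------------
# nucleotide-level statistics


def segregating_sites(catalog: AlleleCatalog, alleles: list[str] | None = None) -> int:
    """Number of nucleotide positions with more than one state."""
    seqs = [catalog.entries[a] for a in (alleles or catalog.allele_ids)]
    if len(seqs) < 2:
        raise ValueError("need at least 2 alleles")
    return sum(len({s[i] for s in seqs}) > 1 for i in range(len(seqs[0])))


def nucleotide_diversity(catalog: AlleleCatalog, alleles: list[str] | None = None) -> float:
    """Mean pairwise proportion of differing nucleotide positions (pi)."""
    seqs = [catalog.entries[a] for a in (alleles or catalog.allele_ids)]
    if len(seqs) < 2:
        raise ValueError("need at least 2 alleles")
    L = len(seqs[0])
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequence length mismatch")
    total = 0.0
    npairs = 0
    for s1, s2 in itertools.combinations(seqs, 2):
        total += sum(c1 != c2 for c1, c2 in zip(s1, s2)) / L
        npairs += 1
    return total / npairs


@lru_cache(maxsize=None)
def _codon_site_fractions(codon: str) -> tuple[float, float]:
    """(syn_sites, nonsyn_sites) of one codon; stop mutants excluded."""
    syn_sites = 0.0
    for pos in range(3):
        syn = nonsyn = 0
        for alt in _NT:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if mutant in _STOPS:
                continue
            if _aa(mutant) == _aa(codon):
                syn += 1
            else:
                nonsyn += 1
        if syn + nonsyn:
            syn_sites += syn / (syn + nonsyn)
    return syn_sites, 3.0 - syn_sites


@lru_cache(maxsize=None)
def _codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(syn_diffs, nonsyn_diffs) averaged over minimal mutational pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked the average falls back to all pathways.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff_pos):
        current = c1
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1:]
            if nxt in _STOPS:
                blocked = True
                break
            if _aa(nxt) == _aa(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        pathways.append((blocked, syn, nonsyn))
    valid = [(s, n) for blocked, s, n in pathways if not blocked]
    if not valid:
        valid = [(s, n) for _, s, n in pathways]
    syn_mean = sum(s for s, _ in valid) / len(valid)
    return syn_mean, len(diff_pos) - syn_mean


def _pair_syn_nonsyn(seq1: str, seq2: str) -> tuple[float, float, float, float]:
    """(syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs) for one allele pair."""
    ss = sn = ds = dn = 0.0
    for i in range(0, len(seq1) - 2, 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        s1, n1 = _codon_site_fractions(c1)
        s2, n2 = _codon_site_fractions(c2)
        ss += (s1 + s2) / 2.0
        sn += (n1 + n2) / 2.0
        d_s, d_n = _codon_pair_differences(c1, c2)
        ds += d_s
        dn += d_n
    return ss, sn, ds, dn


def nei_gojobori(
    catalog: AlleleCatalog,
    alleles: list[str] | None = None,
    frame_offset: int | None = None,
) -> tuple[float, float]:
    """(pi_syn, pi_nonsyn): synonymous / nonsynonymous nucleotide diversity.

    Unweighted Nei-Gojobori proportions (no distance correction): per allele
    pair, synonymous and nonsynonymous sites are the codon-table fractions
    averaged between the two sequences, and differences are averaged with
    equal weight over minimal mutational pathways.  Pairs whose averaged
    site count for a component is zero are excluded from that component's
    mean (with a logged count).
    """
    ids = alleles or catalog.allele_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 alleles")
    offset = catalog.frame_offset if frame_offset is None else frame_offset
    seqs = []
    for a in ids:
        s = catalog.entries[a][offset:]
        seqs.append(s[: 3 * (len(s) // 3)])
    syn_vals, nonsyn_vals = [], []
    skipped_syn = skipped_nonsyn = 0
    for s1, s2 in itertools.combinations(seqs, 2):
        ss, sn, ds, dn = _pair_syn_nonsyn(s1, s2)
        if ss > 0:
            syn_vals.append(ds / ss)
        else:
            skipped_syn += 1
        if sn > 0:
            nonsyn_vals.append(dn / sn)
        else:
            skipped_nonsyn += 1
    if skipped_syn or skipped_nonsyn:
        logger.warning(
            "nei_gojobori: excluded %d pair(s) with zero synonymous and %d "
            "with zero nonsynonymous sites", skipped_syn, skipped_nonsyn,
        )
    if not syn_vals or not nonsyn_vals:
        raise ValueError("no allele pair with defined syn and nonsyn components")
    return float(np.mean(syn_vals)), float(np.mean(nonsyn_vals))


def individual_pss_distance(
    genotype: MultilocusGenotype, catalog: AlleleCatalog, pss_positions: list[int]
) -> float:
    """Mean pairwise amino-acid p-distance at the PSS within one individual."""
    if not pss_positions:
        raise ValueError("no PSS positions configured")
    alleles = sorted(genotype.alleles)
    if len(alleles) < 2:
        raise ValueError("individual carries a single allele; distance undefined")
    peps = [[catalog.peptides[a][p - 1] for p in pss_positions] for a in alleles]
    dists = [
        sum(r1 != r2 for r1, r2 in zip(p1, p2)) / len(pss_positions)
        for p1, p2 in itertools.combinations(peps, 2)
    ]
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# summary table


@dataclass
class SiteDiversity:
    """One row of the per-site diversity summary."""

    site_id: str
    n: int
    A: int
    A_priv: int
    N_S: int | None
    A_R: float | None
    IndA_mean: float
    IndA_sd: float
    IndS_mean: float | None
    S: int | None
    pi: float | None
    pi_syn: float | None
    pi_nonsyn: float | None
    ind_p_distance: float | None


def _summarise(
    dataset: Dataset,
    label: str,
    sites: list[str],
    model: SupertypeModel | None,
    g: int | None,
    pss_positions: list[int] | None,
    a_priv_vs_all: bool,
) -> SiteDiversity:
    genotypes = dataset.site_genotypes(sites)
    alleles = sorted(set().union(*(geno.alleles for geno in genotypes)))
    if a_priv_vs_all and len(sites) == 1:
        A, A_priv = allele_counts(dataset, sites[0])
    else:
        elsewhere: set[str] = set()
        for geno in dataset.genotypes:
            if geno.site_id not in sites:
                elsewhere |= geno.alleles
        A, A_priv = len(alleles), len(set(alleles) - elsewhere)
    sizes = [len(geno.alleles) for geno in genotypes]
    n_s = len({model.supertype_of(a) for a in alleles}) if model else None
    ind_s = (
        float(np.mean([count_supertypes(geno, model) for geno in genotypes]))
        if model
        else None
    )
    a_r = None
    if g is not None:
        n_records = sum(sizes)
        if 1 <= g <= n_records:
            if len(sites) == 1:
                a_r = rarefied_richness(dataset, sites[0], g)
            else:
                pooled = Dataset(
                    catalog=dataset.catalog,
                    genotypes=[
                        MultilocusGenotype(geno.individual_id, "pooled", geno.alleles)
                        for geno in genotypes
                    ],
                )
                a_r = rarefied_richness(pooled, "pooled", g)
        else:
            logger.warning("A_R undefined for %s: g=%s outside record count", label, g)
    s = pi = pi_s = pi_n = None
    if len(alleles) >= 2:
        s = segregating_sites(dataset.catalog, alleles)
        pi = nucleotide_diversity(dataset.catalog, alleles)
        pi_s, pi_n = nei_gojobori(dataset.catalog, alleles)
    pdist = None
    if pss_positions:
        vals = [
            individual_pss_distance(geno, dataset.catalog, pss_positions)
            for geno in genotypes
            if len(geno.alleles) >= 2
        ]
        if len(vals) < len(genotypes):
            logger.info(
                "%s: %d single-allele individual(s) excluded from Ind_p-distance",
                label, len(genotypes) - len(vals),
            )
        pdist = float(np.mean(vals)) if vals else None
    return SiteDiversity(
        site_id=label,
        n=len(genotypes),
        A=A,
        A_priv=A_priv,
        N_S=n_s,
        A_R=a_r,
        IndA_mean=float(np.mean(sizes)),
        IndA_sd=float(np.std(sizes, ddof=1)) if len(sizes) > 1 else 0.0,
        IndS_mean=ind_s,
        S=s,
        pi=pi,
        pi_syn=pi_s,
        pi_nonsyn=pi_n,
        ind_p_distance=pdist,
    )


def diversity_table(
    dataset: Dataset,
    model: SupertypeModel | None = None,
    g: int | None = None,
    pss_positions: list[int] | None = None,
    groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-site diversity summary, with optional pooled group rows.

    ``g`` is the rarefaction draw size in individual-allele records
    (defaults to the smallest per-site record total, so every site row gets
    an A_R).  ``groups`` maps a pooled row label to the sites it spans
    (e.g. native vs invasive).
    """
    if g is None:
        g = min(
            sum(len(geno.alleles) for geno in dataset.site_genotypes([s]))
            for s in dataset.sites
        )
    rows = []
    if groups:
        for label, sites in groups.items():
            rows.append(_summarise(dataset, label, list(sites), model, g, pss_positions, False))
    for site in dataset.sites:
        rows.append(_summarise(dataset, site, [site], model, g, pss_positions, True))
    return pd.DataFrame([vars(r) for r in rows])
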