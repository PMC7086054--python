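"""Core data containers and file I/O for allele catalogs and genotype tables.

The analysis operates on amplicon-typed multigene-family data: each allele
is a fixed-length nucleotide sequence (one reading frame, no indels), and
each individual carries an unphased *set* of alleles of unknown dosage,
because alleles of duplicated MHC loci cannot be assigned to a locus.
Genotypes are therefore presence/absence sets, never allele counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID_NT = set("ACGT")

#: allele-set sizes outside this range trigger a warning (observed range in
#: amplicon-typed multilocus MHC data is 2-6 alleles per individual).
EXPECTED_SET_SIZE = (1, 6)


@dataclass
class AlleleCatalog:
    """Validated allele nucleotide sequences plus their translations.

    Parameters
    ----------
    entries : mapping of allele_id -> uppercase A/C/G/T sequence, all of
        one length ``L``.
    frame_offset : number of bases (0-2) skipped before the first complete
        codon; the trailing incomplete codon is silently trimmed.
    """

    entries: dict[str, str]
    frame_offset: int = 0
    peptides: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not 0 <= self.frame_offset <= 2:
            raise ValueError(f"frame_offset must be 0-2, got {self.frame_offset}")
        if not self.entries:
            raise ValueError("empty allele catalog")
        lengths = {len(s) for s in self.entries.values()}
        if len(lengths) != 1:
            raise ValueError(f"length heterogeneity among alleles: lengths {sorted(lengths)}")
        bad = [a for a, s in self.entries.items() if set(s) - _VALID_NT]
        if bad:
            raise ValueError(f"non-ACGT characters in allele(s): {bad}")
        if not self.peptides:
            self.peptides = {a: self._translate(s) for a, s in self.entries.items()}
        stops = [a for a, p in self.peptides.items() if "*" in p]
        if stops:
            raise ValueError(f"stop codon in translated allele(s): {stops}")

    def _translate(self, seq: str) -> str:
        trimmed = seq[self.frame_offset:]
        trimmed = trimmed[: 3 * (len(trimmed) // 3)]
        return str(Seq(trimmed).translate())

    @property
    def length(self) -> int:
        return len(next(iter(self.entries.values())))

    @property
    def peptide_length(self) -> int:
        return (self.length - self.frame_offset) // 3

    @property
    def allele_ids(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, allele_id: str) -> bool:
        return allele_id in self.entries


@dataclass(frozen=True)
class MultilocusGenotype:
    """One individual's unphased allele set at one sampling site."""

    individual_id: str
    site_id: str
    alleles: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", frozenset(self.alleles))
        if not self.alleles:
            raise ValueError(f"empty genotype for individual {self.individual_id!r}")


@dataclass
class Dataset:
    """An allele catalog plus the multilocus genotypes sampled per site."""

    catalog: AlleleCatalog
    genotypes: list[MultilocusGenotype]
    sites: list[str] = field(default_factory=list)
    coords: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not self.sites:
            seen: list[str] = []
            for g in self.genotypes:
                if g.site_id not in seen:
                    seen.append(g.site_id)
            self.sites = seen
        ids = [g.individual_id for g in self.genotypes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dupes}")
        for g in self.genotypes:
            if g.site_id not in self.sites:
                raise ValueError(f"genotype site {g.site_id!r} not in site list")
            missing = g.alleles - set(self.catalog.entries)
            if missing:
                raise ValueError(
                    f"individual {g.individual_id!r} carries allele(s) absent "
                    f"from catalog: {sorted(missing)}"
                )
            lo, hi = EXPECTED_SET_SIZE
            if not lo <= len(g.alleles) <= hi:
                logger.warning(
                    "individual %s carries %d alleles (outside expected %d-%d)",
                    g.individual_id, len(g.alleles), lo, hi,
                )

    def site_genotypes(self, sites: Iterable[str]) -> list[MultilocusGenotype]:
        wanted = set(sites)
        unknown = wanted - set(self.sites)
        if unknown:
            raise KeyError(f"unknown site(s): {sorted(unknown)}")
        return [g for g in self.genotypes if g.site_id in wanted]

    def n_individuals(self, site: str | None = None) -> int:
        if site is None:
            return len(self.genotypes)
        return sum(g.site_id == site for g in self.genotypes)


# ---------------------------------------------------------------------------
# readers / writers


def read_allele_fasta(path: str | Path, frame_offset: int = 0) -> AlleleCatalog:
    """Read and validate an allele FASTA into an :class:`AlleleCatalog`.

    Records with non-ACGT characters, length differing from the rest, a
    duplicate id, or an in-frame stop codon cause a ``ValueError`` naming the
    offending record(s).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    entries: dict[str, str] = {}
    for rec in records:
        if rec.id in entries:
            raise ValueError(f"duplicate allele id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r}")
        entries[rec.id] = seq
    return AlleleCatalog(entries=entries, frame_offset=frame_offset)


def write_allele_fasta(catalog: AlleleCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for allele_id, seq in catalog.entries.items():
            fh.write(f">{allele_id}\n{seq}\n")


def _sniff_sep(path: Path) -> str:
    head = path.read_text().splitlines()[0]
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_genotype_table(
    path: str | Path,
    catalog: AlleleCatalog,
    coords: Mapping[str, tuple[float, float]] | None = None,
) -> Dataset:
    """Read a genotype table (long or wide form) into a :class:`Dataset`.

    Long form has columns ``individual, site, allele`` (one row per carried
    allele).  Wide form has ``individual, site`` plus one 0/1 column per
    allele id; it is detected by the presence of more than one column named
    after a catalog allele.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if "site" not in df.columns:
        raise ValueError(f"genotype table {path} lacks a 'site' column")
    if "individual" not in df.columns:
        raise ValueError(f"genotype table {path} lacks an 'individual' column")

    allele_cols = [c for c in df.columns if c in catalog]
    if len(allele_cols) > 1:  # wide 0/1 incidence form
        genotypes = []
        for _, row in df.iterrows():
            present = frozenset(a for a in allele_cols if int(row[a]) != 0)
            if not present:
                raise ValueError(f"empty genotype for individual {row['individual']!r}")
            genotypes.append(
                MultilocusGenotype(row["individual"], row["site"], present)
            )
    else:  # long form
        if "allele" not in df.columns:
            raise ValueError(f"genotype table {path} lacks an 'allele' column")
        unknown = sorted(set(df["allele"]) - set(catalog.entries))
        if unknown:
            raise ValueError(f"allele(s) not in catalog: {unknown}")
        genotypes = []
        for (ind, site), grp in df.groupby(["individual", "site"], sort=False):
            genotypes.append(MultilocusGenotype(ind, site, frozenset(grp["allele"])))
    return Dataset(
        catalog=catalog,
        genotypes=genotypes,
        coords=dict(coords) if coords is not None else None,
    )


def write_genotype_table(dataset: Dataset, path: str | Path) -> None:
    """Write genotypes in long form (individual, site, allele), tab-separated."""
    rows = [
        {"individual": g.individual_id, "site": g.site_id, "allele": a}
        for g in dataset.genotypes
        for a in sorted(g.alleles)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_coords(path: str | Path) -> dict[str, tuple[float, float]]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    for col in ("site", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"coordinates file {path} lacks column {col!r}")
    return {str(r["site"]): (float(r["x"]), float(r["y"])) for _, r in df.iterrows()}


def write_coords(coords: Mapping[str, tuple[float, float]], path: str | Path) -> None:
    pd.DataFrame(
        [{"site": s, "x": x, "y": y} for s, (x, y) in coords.items()]
    ).to_csv(path, sep="\t", index=False)


def incidence_matrix(
    dataset: Dataset, site_filter: Iterable[str] | None = None
) -> pd.DataFrame:
    """Individuals x alleles 0/1 incidence matrix.

    Entry ``(i, a)`` is 1 iff individual ``i`` carries allele ``a``.  Columns
    follow catalog order; rows follow genotype order (optionally restricted
    to ``site_filter``).
    """
    genotypes = (
        dataset.genotypes
        if site_filter is None
        else dataset.site_genotypes(site_filter)
    )
    if not genotypes:
        raise ValueError("no individuals match the site filter")
    alleles = dataset.catalog.allele_ids
    mat = np.zeros((len(genotypes), len(alleles)), dtype=np.int8)
    col = {a: j for j, a in enumerate(alleles)}
    for i, g in enumerate(genotypes):
        for a in g.alleles:
            mat[i, col[a]] = 1
    return pd.DataFrame(mat, index=[g.individual_id for g in genotypes], columns=alleles)
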