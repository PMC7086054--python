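import itertools

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from mhcdiv.data import AlleleCatalog, Dataset, MultilocusGenotype
from mhcdiv.diversity import (
    allele_counts,
    diversity_table,
    individual_pss_distance,
    nei_gojobori,
    nucleotide_diversity,
    rarefied_richness,
    segregating_sites,
    _codon_pair_differences,
    _codon_site_fractions,
)


def _catalog(seqs):
    return AlleleCatalog(entries={f"a{i}": s for i, s in enumerate(seqs)})


class TestAlleleCounts:
    def test_single_site_all_private(self, toy_dataset):
        ds = Dataset(
            catalog=toy_dataset.catalog,
            genotypes=[g for g in toy_dataset.genotypes if g.site_id == "north"],
        )
        a, priv = allele_counts(ds, "north")
        assert a == priv == 3

    def test_identical_site_allele_sets_no_private(self, tiny_catalog):
        ds = Dataset(
            catalog=tiny_catalog,
            genotypes=[
                MultilocusGenotype("i1", "X", {"a1", "a2"}),
                MultilocusGenotype("i2", "Y", {"a1", "a2"}),
            ],
        )
        assert allele_counts(ds, "X") == (2, 0)
        assert allele_counts(ds, "Y") == (2, 0)

    def test_unknown_site(self, toy_dataset):
        with pytest.raises(KeyError):
            allele_counts(toy_dataset, "mars")


class TestRarefiedRichness:
    @pytest.fixture
    def site_ds(self, tiny_catalog):
        # records: a1 x2, a2 x1, a3 x1 -> N = 4
        return Dataset(
            catalog=tiny_catalog,
            genotypes=[
                MultilocusGenotype("i1", "S", {"a1", "a2"}),
                MultilocusGenotype("i2", "S", {"a1", "a3"}),
            ],
        )

    def test_g_equals_n_gives_a(self, site_ds):
        assert rarefied_richness(site_ds, "S", 4) == pytest.approx(3.0)

    def test_g_one_gives_one(self, site_ds):
        assert rarefied_richness(site_ds, "S", 1) == pytest.approx(1.0)

    def test_records_211_g2_enumeration(self, site_ds):
        # all C(4,2)=6 two-record subsets: 5/6 + 1/2 + 1/2 = 11/6
        assert rarefied_richness(site_ds, "S", 2) == pytest.approx(11 / 6)

    def test_monotone_in_g(self, site_ds):
        vals = [rarefied_richness(site_ds, "S", g) for g in range(1, 5)]
        assert vals == sorted(vals)

    def test_g_out_of_range(self, site_ds):
        with pytest.raises(ValueError):
            rarefied_richness(site_ds, "S", 5)

    @settings(
        deadline=None,
        derandomize=True,
        max_examples=50,
        # the catalog fixture is read-only, so reuse across examples is safe
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(st.lists(st.integers(min_value=1, max_value=4), min_size=2, max_size=6))
    def test_property_bounds_and_endpoints(self, tiny_catalog, record_counts):
        # build one site whose per-allele record counts are as drawn
        alleles = list(tiny_catalog.entries)[: len(record_counts)]
        genotypes = []
        i = 0
        slots: list[list[str]] = []
        for a, cnt in zip(alleles, record_counts):
            for r in range(cnt):
                if r >= len(slots):
                    slots.append([])
                slots[r].append(a)
        genotypes = [
            MultilocusGenotype(f"i{j}", "S", set(row)) for j, row in enumerate(slots)
        ]
        ds = Dataset(catalog=tiny_catalog, genotypes=genotypes)
        n_total = sum(len(g.alleles) for g in genotypes)
        n_alleles = len({a for g in genotypes for a in g.alleles})
        assert rarefied_richness(ds, "S", 1) == pytest.approx(1.0)
        assert rarefied_richness(ds, "S", n_total) == pytest.approx(n_alleles)
        for g in range(1, n_total + 1):
            val = rarefied_richness(ds, "S", g)
            assert 1.0 - 1e-9 <= val <= n_alleles + 1e-9


class TestSegregatingSitesAndPi:
    def test_identical_sequences_zero(self):
        cat = _catalog(["AAATTT", "AAATTT"])
        assert segregating_sites(cat) == 0
        assert nucleotide_diversity(cat) == 0.0

    def test_small_examples(self):
        assert segregating_sites(_catalog(["AAATTT", "AATTTT"])) == 1
        cat = _catalog(["AAATTT", "AATTTT", "ATTTTT"])
        assert segregating_sites(cat) == 2

    def test_pi_half(self):
        # differ at 3 of 6 positions
        assert nucleotide_diversity(_catalog(["AAAAAC", "AATTTC"])) == pytest.approx(0.5)

    def test_pi_three_sequences(self):
        cat = _catalog(["AAAAAC", "AATTAC", "AAATAC"])
        # pairwise: 2/6, 1/6, 1/6 -> mean 2/9
        assert nucleotide_diversity(cat) == pytest.approx(2 / 9)

    def test_pi_equals_per_position_mismatch_oracle(self, rng):
        # oracle: average over positions of the pairwise mismatch probability
        for _ in range(10):
            seqs = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(5)]
            try:
                cat = _catalog(seqs)
            except ValueError:  # random stop codon
                continue
            n = len(seqs)
            L = 9
            oracle = 0.0
            for pos in range(L):
                col = [s[pos] for s in seqs]
                mismatch = sum(
                    c1 != c2 for c1, c2 in itertools.combinations(col, 2)
                ) / (n * (n - 1) / 2)
                oracle += mismatch / L
            assert nucleotide_diversity(cat) == pytest.approx(oracle)


def oracle_codon_pathways(c1, c2):
    """Independent pathway enumeration using Biopython translation."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diff):
        cur, syn, nonsyn, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if str(Seq(nxt).translate()) == "*":
                blocked = True
                break
            if str(Seq(nxt).translate()) == str(Seq(cur).translate()):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        results.append((blocked, syn, nonsyn))
    ok = [(s, n) for b, s, n in results if not b] or [(s, n) for _, s, n in results]
    return (
        sum(s for s, _ in ok) / len(ok),
        sum(n for _, n in ok) / len(ok),
    )


class TestNeiGojobori:
    def test_synonymous_only_pair(self):
        # TTT vs TTC: Phe/Phe
        syn, nonsyn = nei_gojobori(_catalog(["TTT", "TTC"]))
        assert nonsyn == 0.0
        assert syn > 0.0

    def test_met_ile_pair_is_purely_nonsynonymous(self):
        # ATG has zero synonymous third-position changes; pair-averaged syn
        # sites are 1/3 (from ATA), so the syn component is 0, nonsyn > 0
        syn, nonsyn = nei_gojobori(_catalog(["ATG", "ATA"]))
        assert _codon_site_fractions("ATG")[0] == pytest.approx(0.0)
        assert syn == 0.0
        assert nonsyn > 0.0

    def test_lys_arg_single_nonsyn_difference(self):
        ds, dn = _codon_pair_differences("AAA", "AGA")
        assert (ds, dn) == (0.0, 1.0)

    @pytest.mark.parametrize(
        "c1,c2",
        [
            ("AAA", "AGA"), ("TTT", "TTC"), ("ATG", "ATA"), ("GGG", "CCC"),
            ("TTA", "CTG"), ("AAA", "CCC"), ("TGT", "AGG"), ("CAT", "GTA"),
        ],
    )
    def test_pathway_counts_match_oracle(self, c1, c2):
        assert _codon_pair_differences(c1, c2) == pytest.approx(
            oracle_codon_pathways(c1, c2)
        )

    def test_differences_conserve_total_mismatches(self, rng):
        nonstop = [
            "".join(c)
            for c in itertools.product("ACGT", repeat=3)
            if "".join(c) not in ("TAA", "TAG", "TGA")
        ]
        for _ in range(100):
            c1, c2 = rng.choice(nonstop, 2)
            ds, dn = _codon_pair_differences(c1, c2)
            assert ds + dn == pytest.approx(sum(a != b for a, b in zip(c1, c2)))

    def test_site_fractions_sum_to_three(self):
        for codon in ("AAA", "TTT", "ATG", "TGG", "CGA"):
            s, n = _codon_site_fractions(codon)
            assert s + n == pytest.approx(3.0)


class TestIndividualPssDistance:
    @pytest.fixture
    def catalog(self):
        # peptides: MAAA, MAAA, MWWA, FAWA (positions 1..4)
        return AlleleCatalog(
            entries={
                "a1": "ATGGCTGCTGCT",
                "a2": "ATGGCTGCTGCA",
                "a3": "ATGTGGTGGGCT",
                "a4": "TTTGCTTGGGCT",
            }
        )

    def test_identical_at_pss_zero(self, catalog):
        g = MultilocusGenotype("i", "S", {"a1", "a2"})
        assert individual_pss_distance(g, catalog, [1, 2, 3, 4]) == 0.0

    def test_all_pss_differ_is_one(self, catalog):
        g = MultilocusGenotype("i", "S", {"a2", "a4"})
        # a2 MAAA vs a4 FAWA at positions 1 and 3: both differ
        assert individual_pss_distance(g, catalog, [1, 3]) == 1.0

    def test_three_allele_mean(self, catalog):
        g = MultilocusGenotype("i", "S", {"a1", "a3", "a4"})
        # at PSS [1,2,3]: a1=MAA, a3=MWW, a4=FAW
        # pairs: (a1,a3)=2/3, (a1,a4)=2/3, (a3,a4)=2/3
        assert individual_pss_distance(g, catalog, [1, 2, 3]) == pytest.approx(2 / 3)

    def test_single_allele_undefined(self, catalog):
        g = MultilocusGenotype("i", "S", {"a1"})
        with pytest.raises(ValueError):
            individual_pss_distance(g, catalog, [1])


class TestDiversityTable:
    def test_planted_values_recovered(self):
        cat = _catalog(["AAATTT", "AATTTT", "ATTTTT", "AAATTC"])
        ds = Dataset(
            catalog=cat,
            genotypes=[
                MultilocusGenotype("i1", "X", {"a0", "a1"}),
                MultilocusGenotype("i2", "X", {"a0", "a3"}),
                MultilocusGenotype("i3", "Y", {"a2", "a3"}),
            ],
        )
        table = diversity_table(ds).set_index("site_id")
        assert table.loc["X", "A"] == 3
        assert table.loc["X", "A_priv"] == 2  # a0 and a1 only in X
        assert table.loc["X", "n"] == 2
        sub = ["a0", "a1", "a3"]
        assert table.loc["X", "S"] == segregating_sites(cat, sub)
        assert table.loc["X", "pi"] == pytest.approx(nucleotide_diversity(cat, sub))

    def test_single_individual_site_row_flagged(self, tiny_catalog):
        ds = Dataset(
            catalog=tiny_catalog,
            genotypes=[
                MultilocusGenotype("i1", "X", {"a1"}),
                MultilocusGenotype("i2", "Y", {"a1", "a3"}),
            ],
        )
        table = diversity_table(ds).set_index("site_id")
        assert table.loc["X", "n"] == 1
        assert np.isnan(table.loc["X", "S"])  # single allele: undefined
        assert np.isnan(table.loc["X", "pi"])

    def test_pooled_group_rows(self, toy_dataset):
        table = diversity_table(
            toy_dataset, groups={"all": ["north", "south"]}
        ).set_index("site_id")
        assert table.loc["all", "n"] == 5
        assert table.loc["all", "A"] == 4
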