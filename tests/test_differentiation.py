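import math

import numpy as np
import pandas as pd
import pytest

from mhcdiv.data import AlleleCatalog, Dataset, MultilocusGenotype
from mhcdiv.differentiation import (
    DiploidPanel,
    geographic_distance,
    identity_between_individuals,
    mantel,
    partial_mantel,
    rho_global,
    rho_pairwise,
    rho_permutation_test,
    transform_rho,
)


@pytest.fixture
def two_allele_catalog():
    return AlleleCatalog(entries={"a1": "ATGGCT", "a2": "TGGTGG"})


def _fixed_sites_dataset(cat, n_per_site=4):
    genotypes = [
        MultilocusGenotype(f"x{i}", "X", {"a1"}) for i in range(n_per_site)
    ] + [
        MultilocusGenotype(f"y{i}", "Y", {"a2"}) for i in range(n_per_site)
    ]
    return Dataset(catalog=cat, genotypes=genotypes)


class TestIdentity:
    def test_identical_singletons(self):
        assert identity_between_individuals({"a"}, {"a"}) == 1.0

    def test_disjoint_sets(self):
        assert identity_between_individuals({"a", "b"}, {"c"}) == 0.0

    def test_partial_overlap_enumeration(self):
        assert identity_between_individuals({"a", "b"}, {"a", "c"}) == 0.25

    def test_diploid_identity(self):
        g1 = {"L1": ("1", "2"), "L2": ("1", "1")}
        g2 = {"L1": ("1", "3"), "L2": ("2", "2")}
        # L1: matches 1 of 4 draws; L2: 0 of 4
        assert identity_between_individuals(g1, g2) == pytest.approx(0.125)

    def test_diploid_missing_locus_skipped(self):
        g1 = {"L1": ("1", "1"), "L2": None}
        g2 = {"L1": ("1", "1"), "L2": ("2", "2")}
        assert identity_between_individuals(g1, g2) == 1.0

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            identity_between_individuals(set(), {"a"})


class TestRho:
    def test_fixed_distinct_sites_rho_one(self, two_allele_catalog):
        ds = _fixed_sites_dataset(two_allele_catalog)
        assert rho_pairwise(ds, "X", "Y") == pytest.approx(1.0)
        rho, tr = rho_global(ds)
        assert rho == pytest.approx(1.0)
        assert tr == math.inf

    def test_identical_composition_near_zero(self, tiny_catalog):
        # cross-site pairs include each individual's literal twin, so the
        # between-individual estimator carries a small negative O(1/n) bias
        # for identical compositions; it vanishes as n grows
        reps = 12
        genotypes = []
        for r in range(reps):
            genotypes += [
                MultilocusGenotype(f"x{r}a", "X", {"a1", "a2"}),
                MultilocusGenotype(f"x{r}b", "X", {"a3"}),
                MultilocusGenotype(f"y{r}a", "Y", {"a1", "a2"}),
                MultilocusGenotype(f"y{r}b", "Y", {"a3"}),
            ]
        ds = Dataset(catalog=tiny_catalog, genotypes=genotypes)
        rho = rho_pairwise(ds, "X", "Y")
        assert rho < 0  # twin pairs pull Q3 above Q2
        assert abs(rho) < 2 / reps

    def test_label_permuted_pool_near_zero(self):
        from mhcdiv.simulate import make_allele_catalog, make_populations

        cat, _ = make_allele_catalog(20, planted_k=4, seed=0)
        vals = []
        for seed in range(8):
            ds, _ = make_populations(cat, 2, 30, divergence=0.0, seed=seed)
            vals.append(rho_pairwise(ds, "S1", "S2"))
        assert abs(np.mean(vals)) < 0.02

    def test_diploid_heterozygous_disjoint_pairs(self):
        # all X individuals 1/2, all Y individuals 3/4: Q2 = 0.5 (two random
        # gene copies from different same-site individuals match half the
        # time), Q3 = 0, so Rho = 0.5 under the between-individual identity
        # definition
        genotypes = {}
        site_of = {}
        for i in range(3):
            genotypes[f"x{i}"] = {"L1": ("1", "2")}
            site_of[f"x{i}"] = "X"
            genotypes[f"y{i}"] = {"L1": ("3", "4")}
            site_of[f"y{i}"] = "Y"
        panel = DiploidPanel(loci=["L1"], site_of=site_of, genotypes=genotypes)
        assert rho_pairwise(panel, "X", "Y") == pytest.approx(0.5)

    def test_diploid_fixed_homozygous_disjoint_rho_one(self):
        genotypes = {}
        site_of = {}
        for i in range(3):
            genotypes[f"x{i}"] = {"L1": ("1", "1")}
            site_of[f"x{i}"] = "X"
            genotypes[f"y{i}"] = {"L1": ("2", "2")}
            site_of[f"y{i}"] = "Y"
        panel = DiploidPanel(loci=["L1"], site_of=site_of, genotypes=genotypes)
        assert rho_pairwise(panel, "X", "Y") == pytest.approx(1.0)

    def test_duplication_invariance_at_scale(self, tiny_catalog, rng):
        # duplicating every individual leaves Rho nearly unchanged once the
        # per-site sample is large enough for twin pairs to be negligible
        alleles = list(tiny_catalog.entries)
        genotypes = []
        for i in range(10):
            genotypes.append(
                MultilocusGenotype(
                    f"x{i}", "X",
                    set(rng.choice(alleles[:3], size=2, replace=False)),
                )
            )
            genotypes.append(
                MultilocusGenotype(
                    f"y{i}", "Y",
                    set(rng.choice(alleles[1:], size=2, replace=False)),
                )
            )
        ds = Dataset(catalog=tiny_catalog, genotypes=genotypes)
        base = rho_pairwise(ds, "X", "Y")
        doubled = Dataset(
            catalog=tiny_catalog,
            genotypes=[
                MultilocusGenotype(f"{g.individual_id}-{r}", g.site_id, g.alleles)
                for g in genotypes
                for r in (1, 2)
            ],
        )
        assert rho_pairwise(doubled, "X", "Y") == pytest.approx(base, abs=0.05)

    def test_permutation_p_bounds_and_detection(self, two_allele_catalog):
        ds = _fixed_sites_dataset(two_allele_catalog, n_per_site=5)
        rho, p = rho_permutation_test(ds, "X", "Y", n_perm=999, seed=0)
        assert rho == pytest.approx(1.0)
        assert 1 / 1000 <= p <= 0.02

    def test_single_site_global_raises(self, tiny_catalog):
        ds = Dataset(
            catalog=tiny_catalog,
            genotypes=[
                MultilocusGenotype("i1", "X", {"a1"}),
                MultilocusGenotype("i2", "X", {"a2"}),
            ],
        )
        with pytest.raises(ValueError):
            rho_global(ds)

    def test_transform(self):
        assert transform_rho(0.0) == 0.0
        assert transform_rho(0.5) == pytest.approx(1.0)
        assert transform_rho(1.0) == math.inf


def _random_distance(rng, n=7):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


class TestMantel:
    def test_identical_matrices_r_one(self, rng):
        m = _random_distance(rng)
        r, _ = mantel(m, m, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        m = _random_distance(rng)
        r, _ = mantel(m, 3.0 * m + 2.0, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_negated_matrix_r_minus_one_p_near_one(self, rng):
        m = _random_distance(rng)
        r, p = mantel(m, -m, n_perm=199, seed=0)
        assert r == pytest.approx(-1.0)
        assert p > 0.9

    def test_independent_matrices_r_near_zero(self):
        rs = []
        for seed in range(30):
            r_ = np.random.default_rng(seed)
            r, _ = mantel(_random_distance(r_), _random_distance(r_), n_perm=49, seed=seed)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.15

    def test_constant_matrix_undefined(self):
        m = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="constant"):
            mantel(m, np.zeros((4, 4)) + np.eye(4) * 0, n_perm=9, seed=0)

    def test_accepts_dataframe(self, rng):
        m = _random_distance(rng)
        df = pd.DataFrame(m, index=list("abcdefg"), columns=list("abcdefg"))
        r, _ = mantel(df, df, n_perm=49, seed=0)
        assert r == pytest.approx(1.0)


class TestPartialMantel:
    def test_constant_covariate_reduces_to_simple(self, rng):
        m1, m2 = _random_distance(rng), _random_distance(rng)
        m3 = np.ones((7, 7)) - np.eye(7)
        r_simple, _ = mantel(m1, m2, n_perm=49, seed=3)
        r_partial, _ = partial_mantel(m1, m2, m3, n_perm=49, seed=3)
        assert r_partial == pytest.approx(r_simple)

    def test_covariate_equal_to_m1_degenerate(self, rng):
        m1 = _random_distance(rng)
        m2 = _random_distance(rng)
        with pytest.raises(ValueError, match="collinear"):
            partial_mantel(m1, m2, m1, n_perm=9, seed=0)

    def test_controls_for_shared_structure(self):
        # m1 = m3 + noise, m2 independent: partial r should sit near 0
        rs = []
        for seed in range(20):
            r_ = np.random.default_rng(seed)
            m3 = _random_distance(r_)
            noise = _random_distance(r_) * 0.1
            m1 = m3 + noise
            m2 = _random_distance(r_)
            r, _ = partial_mantel(m1, m2, m3, n_perm=19, seed=seed)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.15


class TestGeographicDistance:
    def test_identical_points_zero(self):
        d = geographic_distance({"a": (1.0, 2.0), "b": (1.0, 2.0)})
        assert d.loc["a", "b"] == 0.0

    def test_quarter_meridian(self):
        d = geographic_distance({"a": (0.0, 0.0), "b": (0.0, 90.0)}, lonlat=True)
        assert d.loc["a", "b"] == pytest.approx(10007.5, rel=1e-3)

    def test_triangle_inequality(self, rng):
        coords = {f"s{i}": tuple(rng.uniform(-50, 50, 2)) for i in range(6)}
        for lonlat in (False, True):
            d = geographic_distance(coords, lonlat=lonlat)
            sites = list(coords)
            for a in sites:
                for b in sites:
                    for c in sites:
                        assert d.loc[a, c] <= d.loc[a, b] + d.loc[b, c] + 1e-9

    def test_missing_site(self):
        with pytest.raises(KeyError):
            geographic_distance({"a": (0, 0)}, sites=["a", "b"])
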