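"""hSNC calling, region-to-gene assignment, density randomization tests,
Fisher overlaps and the W->S composition check."""
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regarch.hsnc import (
    HsncSite,
    call_fixed_differences,
    classify_ws,
    enhancer_density_randomization,
    gbgc_ws_test,
    gene_overlap_fisher,
    hits_count_randomization,
    hsnc_density,
    simulate_universe_densities,
)


def panel_rows(pos, rows):
    """rows: list of (species, allele_counts, n_pass, n_total)."""
    return [("chr1", pos, sp, ac, np_, nt) for sp, ac, np_, nt in rows]


def make_panel(all_rows):
    return pd.DataFrame(
        all_rows,
        columns=["chrom", "pos", "species", "allele_counts", "n_pass", "n_total"],
    )


class TestCallFixedDifferences:
    def test_clean_fixed_difference(self):
        panel = make_panel(
            panel_rows(
                100,
                [
                    ("human", "A=19", 19, 19),
                    ("chimpanzee", "G=61", 61, 61),
                    ("gorilla", "G=42", 42, 42),
                    ("orangutan", "G=27", 27, 27),
                    ("macaque", "G=30", 30, 30),
                ],
            )
        )
        sites, audit = call_fixed_differences(panel)
        assert len(sites) == 1
        assert sites[0].human_allele == "A" and sites[0].other_allele == "G"

    def test_895_percent_is_polymorphic(self):
        panel = make_panel(
            panel_rows(
                100,
                [
                    ("human", "A=17;G=2", 19, 19),  # 89.5% majority
                    ("chimpanzee", "G=61", 61, 61),
                ],
            )
        )
        sites, audit = call_fixed_differences(panel)
        assert sites == []
        assert audit.loc[0, "call"] == "polymorphic"

    def test_exactly_90_percent_is_monomorphic(self):
        panel = make_panel(
            panel_rows(
                100,
                [
                    ("human", "A=18;G=2", 20, 20),  # 90.0% passes
                    ("chimpanzee", "G=61", 61, 61),
                ],
            )
        )
        sites, _ = call_fixed_differences(panel)
        assert len(sites) == 1

    def test_triallelic_removed(self):
        panel = make_panel(
            panel_rows(
                100,
                [
                    ("human", "A=19", 19, 19),
                    ("chimpanzee", "G=61", 61, 61),
                    ("gorilla", "C=42", 42, 42),
                ],
            )
        )
        sites, audit = call_fixed_differences(panel)
        assert sites == []
        assert audit.loc[0, "call"] == "triallelic"

    def test_indel_removed(self):
        panel = make_panel(
            panel_rows(
                100,
                [
                    ("human", "AT=19", 19, 19),
                    ("chimpanzee", "G=61", 61, 61),
                ],
            )
        )
        sites, audit = call_fixed_differences(panel)
        assert audit.loc[0, "call"] == "indel"

    def test_insufficient_data_rejected(self):
        panel = make_panel(
            panel_rows(
                100,
                [
                    ("human", "A=5", 5, 19),  # under half with data
                    ("chimpanzee", "G=61", 61, 61),
                ],
            )
        )
        sites, audit = call_fixed_differences(panel)
        assert audit.loc[0, "call"] == "insufficient_data"

    def test_missing_human_population(self):
        panel = make_panel(panel_rows(1, [("chimpanzee", "G=61", 61, 61)]))
        with pytest.raises(ValueError, match="human"):
            call_fixed_differences(panel)

    def test_matches_brute_force_on_enumerated_toy_panels(self):
        """Exhaustive 2-species x 3-individual panels: the caller agrees
        with a from-scratch rule evaluation at every configuration."""

        def brute(h_counts, c_counts, h_pass, c_pass, n=3):
            for counts, npass in ((h_counts, h_pass), (c_counts, c_pass)):
                kept = sum(counts.values())
                if npass < 0.5 * n or kept == 0:
                    return "insufficient_data"
                major = max(counts.values())
                if major < 0.9 * kept:
                    return "polymorphic"
            alleles = set(h_counts) | set(c_counts)
            if len(alleles) > 2:
                return "triallelic"
            h_major = max(h_counts, key=lambda a: (h_counts[a], a))
            c_major = max(c_counts, key=lambda a: (c_counts[a], a))
            return "hSNC" if h_major != c_major else "not_fixed_difference"

        allele_opts = [{"A": 3}, {"G": 3}, {"A": 2, "G": 1}, {"C": 3}]
        pass_opts = [1, 2, 3]
        for h_c, c_c, h_p, c_p in product(
            allele_opts, allele_opts, pass_opts, pass_opts
        ):
            rows = panel_rows(
                5,
                [
                    ("human", ";".join(f"{a}={n}" for a, n in h_c.items()), h_p, 3),
                    ("chimpanzee", ";".join(f"{a}={n}" for a, n in c_c.items()), c_p, 3),
                ],
            )
            sites, audit = call_fixed_differences(make_panel(rows))
            expected = brute(h_c, c_c, h_p, c_p)
            got = audit.loc[0, "call"]
            assert got == expected, (h_c, c_c, h_p, c_p, got, expected)


class TestAssignRegions:
    @pytest.fixture()
    def regions(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [110_000, 96_000, 500_000],
                "end": [111_000, 96_500, 500_800],
            }
        )

    def test_proximity_and_interaction(self, genes_frame, regions):
        from regarch.hsnc import assign_regions_to_genes

        inter = pd.DataFrame(
            {
                "chrom_a": ["chr1"],
                "start_a": [500_000],
                "end_a": [500_800],
                "chrom_b": ["chr1"],
                "start_b": [320_000],
                "end_b": [321_000],
                "source": ["HiC"],
            }
        )
        out = assign_regions_to_genes(regions, genes_frame, inter)
        # region 0 inside gene A; region 1 is 4 kb upstream of A; region 2
        # interacts with gene B's body
        assert out == {"A", "B"}

    def test_gbgc_filter_removes_region(self, genes_frame, regions):
        from regarch.hsnc import assign_regions_to_genes

        tracts = pd.DataFrame(
            {"chrom": ["chr1"], "start": [109_000], "end": [112_000]}
        )
        out = assign_regions_to_genes(
            regions.iloc[[0]], genes_frame, None, gbgc_tracts=tracts
        )
        assert out == set()


class TestDensity:
    def test_simple_density(self):
        enh = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000], "name": ["e"]}
        )
        sites = [HsncSite("chr1", p, "A", "G") for p in (10, 500, 999)]
        out = hsnc_density(enh, sites)
        assert out[0].count == 3
        assert out[0].density == pytest.approx(0.003)

    def test_half_open_boundaries_match_brute_force(self):
        rng = np.random.default_rng(61)
        enh = pd.DataFrame(
            {"chrom": "chr1", "start": [100, 400], "end": [300, 500],
             "name": ["a", "b"]}
        )
        positions = rng.integers(0, 600, 300)
        sites = [HsncSite("chr1", int(p), "A", "G") for p in positions]
        out = hsnc_density(enh, sites)
        for res, (s, e) in zip(out, [(100, 300), (400, 500)]):
            brute = sum(1 for p in positions if s <= p < e)
            assert res.count == brute
        # boundary semantics: start included, end excluded
        edge = hsnc_density(enh, [HsncSite("chr1", 100, "A", "G"),
                                  HsncSite("chr1", 300, "A", "G")])
        assert edge[0].count == 1

    def test_zero_length_rejected(self):
        enh = pd.DataFrame({"chrom": ["chr1"], "start": [5], "end": [5]})
        with pytest.raises(ValueError):
            hsnc_density(enh, [])


class TestDensityRandomization:
    def test_single_enhancer_universe_p_one(self):
        enh = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000], "name": ["e"]}
        )
        sites = [HsncSite("chr1", p, "A", "G") for p in (1, 2, 3)]
        result, dens = enhancer_density_randomization(
            enh, enh, sites, n_sim=500, seed=0
        )
        assert result.p[0] == 1.0

    def test_matches_binomial_tail(self):
        """Two equal-length enhancers, all 6 changes in A: the empirical p
        matches P(Bin(6, 1/2) >= 6) = 1/64 within 3 Monte-Carlo SEs."""
        uni = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 2000], "end": [1000, 3000],
             "name": ["A", "B"]}
        )
        sites = [HsncSite("chr1", p, "A", "G") for p in range(100, 700, 100)]
        n_sim = 10_000
        result, dens = enhancer_density_randomization(
            uni.iloc[[0]], uni, sites, n_sim=n_sim, seed=1
        )
        exact = (0.5) ** 6
        se = np.sqrt(exact * (1 - exact) / n_sim)
        assert abs(result.p[0] - exact) <= 3 * se

    def test_zero_density_p_one(self):
        uni = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 2000], "end": [1000, 3000],
             "name": ["A", "B"]}
        )
        sites = [HsncSite("chr1", p, "A", "G") for p in (2100, 2200)]
        result, _ = enhancer_density_randomization(
            uni.iloc[[0]], uni, sites, n_sim=200, seed=2
        )
        assert result.p[0] == 1.0

    def test_empty_universe_rejected(self):
        uni = pd.DataFrame(
            {"chrom": "chr1", "start": [0], "end": [1000], "name": ["A"]}
        )
        with pytest.raises(ValueError, match="no hSNC"):
            enhancer_density_randomization(uni, uni, [], n_sim=10, seed=0)


class TestHitsCount:
    def test_zero_observed_hits_p_one(self):
        rng = np.random.default_rng(67)
        sims = rng.random((500, 10))
        obs = np.zeros(10)
        out = hits_count_randomization(sims, obs)
        assert out.observed_hits == 0
        assert out.global_p == 1.0

    def test_enhancer_above_simulated_maximum_is_hit(self):
        """One enhancer above its simulated maximum among 100: it is a
        hit, and the global p equals the fraction of simulations with at
        least one hit (direct enumeration)."""
        rng = np.random.default_rng(71)
        n_sim, n_enh = 400, 100
        sims = rng.random((n_sim, n_enh))
        obs = sims.max(axis=0).copy()
        obs[1:] = 0.0
        obs[0] += 1.0
        out = hits_count_randomization(sims, obs, alpha=0.05)
        assert out.observed_hits == 1
        critical = out.critical_density
        enum = np.mean([(row >= critical).sum() >= 1 for row in sims])
        assert out.global_p == pytest.approx(enum)

    def test_worked_critical_value_position(self):
        """100 enhancers, 10,000 simulations, alpha 5%: the critical value
        is the 5th largest simulated density."""
        rng = np.random.default_rng(73)
        sims = rng.random((10_000, 100))
        out = hits_count_randomization(sims, np.zeros(100), alpha=0.05)
        expected = np.sort(sims, axis=0)[-5, :]
        np.testing.assert_allclose(out.critical_density, expected)

    def test_lower_tail_flag(self):
        # literal smallest-to-largest reading: 5th smallest at
        # ceil(0.05/10 * 1000) = 5
        rng = np.random.default_rng(79)
        sims = rng.random((1000, 10))
        out = hits_count_randomization(sims, np.zeros(10), tail="lower")
        expected = np.sort(sims, axis=0)[4, :]
        np.testing.assert_allclose(out.critical_density, expected)

    def test_null_calibration(self):
        """Observed densities drawn as one extra simulation: the global p
        is roughly uniform (mean near 0.5) across 200 fixtures."""
        rng = np.random.default_rng(83)
        lengths = rng.integers(500, 1500, 400).astype(float)
        pvals = []
        for _ in range(150):
            sims = simulate_universe_densities(lengths, 2000, 201, rng)
            obs, sims = sims[0], sims[1:]
            out = hits_count_randomization(sims, obs, alpha=0.05, n_tests=1)
            pvals.append(out.global_p)
        assert abs(np.mean(pvals) - 0.5) < 0.08
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestFisherAndWs:
    def test_venn_table_odds_ratio(self):
        """The 2x2 table (14, 42, 16, 62) gives OR ~ 1.29 (1.3 at one
        decimal) and a non-significant one-tailed p."""
        universe = {f"g{i}" for i in range(134)}
        sel = {f"g{i}" for i in range(56)}
        hsnc_genes = {f"g{i}" for i in range(14)} | {
            f"g{i}" for i in range(56, 72)
        }
        out = gene_overlap_fisher(sel, hsnc_genes, universe, sided="one")
        assert out["table"].tolist() == [[14, 42], [16, 62]]
        assert out["odds_ratio"] == pytest.approx(1.2917, abs=1e-4)
        assert round(out["odds_ratio"], 1) == 1.3
        assert out["p"] > 0.05

    def test_degenerate_overlap_flagged(self):
        universe = {f"g{i}" for i in range(20)}
        half = {f"g{i}" for i in range(10)}
        out = gene_overlap_fisher(half, half, universe)
        assert out["odds_ratio_unbounded"]

    def test_calibration_under_random_sets(self):
        rng = np.random.default_rng(89)
        universe = {f"g{i}" for i in range(200)}
        pvals = []
        for _ in range(200):
            a = set(rng.choice(sorted(universe), 50, replace=False))
            b = set(rng.choice(sorted(universe), 50, replace=False))
            pvals.append(gene_overlap_fisher(a, b, universe, sided="one")["p"])
        # exact discrete test is conservative; mean should sit near 0.5-0.6
        assert 0.4 < np.mean(pvals) < 0.7

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            gene_overlap_fisher(set(), set(), set())

    @pytest.mark.parametrize(
        "anc,der,expected",
        [("A", "G", "W->S"), ("C", "A", "S->W"), ("A", "T", "W->W"),
         ("G", "C", "S->S")],
    )
    def test_ws_classification(self, anc, der, expected):
        assert classify_ws(anc, der) == expected

    def test_ws_invalid_allele(self):
        with pytest.raises(ValueError):
            classify_ws("N", "A")

    def test_gbgc_all_ws_focal(self):
        focal = [HsncSite("chr1", i, "G", "A") for i in range(20)]  # all W->S
        background = [HsncSite("chr1", i, "A", "T") for i in range(20)]
        out = gbgc_ws_test(focal, background)
        assert out["p"] < 1e-5
        # hypergeometric closed form for the all-or-nothing table
        exact = stats.hypergeom.sf(19, 40, 20, 20)  # P(X >= 20)
        assert out["p"] == pytest.approx(exact, rel=1e-9)

    def test_gbgc_identical_composition(self):
        focal = [HsncSite("chr1", i, "G", "A") for i in range(10)] + [
            HsncSite("chr1", i, "A", "C") for i in range(10)
        ]
        out = gbgc_ws_test(focal, list(focal))
        assert out["odds_ratio"] == pytest.approx(1.0)
        assert out["p"] > 0.5
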