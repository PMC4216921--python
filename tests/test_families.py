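"""Compensation permutation test, genomic clusters, and randomization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import codonbalance as cb
from codonbalance.core import TrnaGene
from codonbalance.families import (
    FamilySkipped,
    cluster_randomization_test,
    compensation_screen,
    compensation_test,
    compensation_vs_clustering,
    define_clusters,
)


def _mirror_family(rng, n_per_cluster=3, n_stages=6, noise=0.05):
    traj = np.linspace(0.2, 0.8, n_stages)
    rows = []
    for i in range(2 * n_per_cluster):
        f = traj if i < n_per_cluster else 1 - traj
        rows.append(rng.lognormal(3, 0.2) * f * np.exp(rng.normal(0, noise, n_stages)))
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(2 * n_per_cluster)])


class TestCompensationTest:
    def test_mirror_clusters_detected_and_recovered(self, rng):
        expr = _mirror_family(rng, noise=0.0)
        res = compensation_test(expr, "fam", seed=0)
        n = len(expr)
        assert len(res.observed_correlations) == n * (n - 1) // 2
        # within-cluster rho = +1, cross-cluster rho = -1
        assert sorted(np.round(res.observed_correlations, 9)) == \
            [-1.0] * 9 + [1.0] * 6
        assert res.p_raw < 0.05 and res.significant
        a, b = map(frozenset, res.expression_clusters)
        assert {a, b} == {frozenset({"g0", "g1", "g2"}),
                          frozenset({"g3", "g4", "g5"})}

    def test_full_enumeration_null_is_centered(self, rng):
        expr = pd.DataFrame(rng.lognormal(3, 1, (4, 6)))
        res = compensation_test(expr, "f", seed=0)
        # antisymmetry under order reversal makes the enumerated null mean 0
        assert abs(res.null_correlations.mean()) < 1e-12
        assert len(res.null_correlations) == 6 * 720

    def test_constant_gene_dropped_with_warning(self, rng, caplog):
        expr = pd.DataFrame(rng.lognormal(3, 1, (4, 6)),
                            index=["a", "b", "c", "d"])
        expr.loc["a"] = 5.0
        with caplog.at_level("WARNING"):
            res = compensation_test(expr, "fam", seed=0)
        assert res.n_genes == 3
        assert "constant" in caplog.text

    def test_too_few_genes_skipped(self, rng):
        expr = pd.DataFrame(rng.lognormal(3, 1, (2, 6)))
        with pytest.raises(FamilySkipped):
            compensation_test(expr, "tiny", seed=0)

    def test_needs_four_stages(self, rng):
        expr = pd.DataFrame(rng.lognormal(3, 1, (4, 3)))
        with pytest.raises(ValueError, match="stages"):
            compensation_test(expr, "f", seed=0)

    def test_sampled_null_reproducible_beyond_cap(self, rng):
        expr = pd.DataFrame(rng.lognormal(3, 1, (4, 7)))  # 7! > 720
        r1 = compensation_test(expr, "f", seed=5)
        r2 = compensation_test(expr, "f", seed=5)
        np.testing.assert_array_equal(r1.null_correlations, r2.null_correlations)
        assert len(r1.null_correlations) == 6 * 720


class TestCompensationScreen:
    def test_bonferroni_formula_and_report_cutoff(self, rng):
        fams = {f"f{i}": pd.DataFrame(rng.lognormal(3, 1, (7, 6)))
                for i in range(5)}
        fams["small"] = pd.DataFrame(rng.lognormal(3, 1, (4, 6)))
        fams["skip"] = pd.DataFrame(rng.lognormal(3, 1, (2, 6)))
        screen = compensation_screen(fams, seed=1)
        assert len(screen.reported) == 5
        for r in screen.reported:
            assert r.p_corrected == pytest.approx(min(1.0, 5 * r.p_raw))
        assert [r.family_id for r in screen.tested_small] == ["small"]
        assert "skip" in screen.skipped

    def test_no_eligible_families_warns(self, rng, caplog):
        fams = {"small": pd.DataFrame(rng.lognormal(3, 1, (4, 6)))}
        with caplog.at_level("WARNING"):
            screen = compensation_screen(fams, seed=0)
        assert screen.reported == [] and "no families" in caplog.text


def _gene(gene_id, chrom, start, family="G-GCC", length=72):
    isotype, _, anticodon = family.rpartition("-")
    return TrnaGene(gene_id, chrom, start, start + length, "+", anticodon, isotype)


class TestDefineClusters:
    def test_chaining_example(self):
        genes = [_gene("g1", "chr1", 0), _gene("g2", "chr1", 5_072),
                 _gene("g3", "chr1", 10_144), _gene("g4", "chr1", 30_216)]
        cs = define_clusters(genes, gap_kb=7.5)
        assert cs.clusters == [["g1", "g2", "g3"]]

    def test_all_isolated(self):
        genes = [_gene(f"g{i}", "chr1", i * 10_000) for i in range(5)]
        assert define_clusters(genes, gap_kb=7.5).n_clusters == 0

    def test_chromosomes_never_mix(self):
        genes = [_gene("g1", "chr1", 100), _gene("g2", "chr2", 100)]
        assert define_clusters(genes, gap_kb=7.5).n_clusters == 0

    def test_matches_brute_force_single_linkage(self, rng):
        """Oracle: connected components of the pairwise gap<=threshold graph
        (equivalent for non-nested fixed-length intervals)."""
        for trial in range(100):
            n = 50
            starts = np.sort(rng.integers(0, 400_000, n))
            chroms = rng.choice(["chr1", "chr2"], n)
            genes = [_gene(f"g{i}", chroms[i], int(starts[i]) + 200 * i)
                     for i in range(n)]
            cs = define_clusters(genes, gap_kb=7.5)
            # brute force over all pairs
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    gi, gj = genes[i], genes[j]
                    if gi.chrom != gj.chrom:
                        continue
                    gap = max(gj.start - gi.end, gi.start - gj.end)
                    if gap <= 7_500:
                        parent[find(i)] = find(j)
            comps: dict[int, set] = {}
            for i in range(n):
                comps.setdefault(find(i), set()).add(genes[i].gene_id)
            expected = {frozenset(c) for c in comps.values() if len(c) >= 2}
            assert {frozenset(c) for c in cs.clusters} == expected

    def test_output_is_a_partition(self, small_sim):
        _, genome, *_ = small_sim
        cs = define_clusters(genome.trna_genes)
        flat = [g for cl in cs.clusters for g in cl]
        assert len(flat) == len(set(flat))
        assert all(len(cl) >= 2 for cl in cs.clusters)


class TestClusterRandomization:
    def test_reproducible_under_seed(self, small_sim):
        _, genome, *_ = small_sim
        r1 = cluster_randomization_test(genome.trna_genes, n_rand=50, seed=3)
        r2 = cluster_randomization_test(genome.trna_genes, n_rand=50, seed=3)
        np.testing.assert_array_equal(r1.null_pcts, r2.null_pcts)

    def test_family_pure_layout_is_extreme(self):
        cfg = cb.SimConfig(n_pc_genes=20, n_trna_genes=150, n_families=20,
                           seed=5, mean_cds_codons=50, clustered_fraction=1.0,
                           cluster_family_bias=1.0,
                           family_size_concentration=50.0)
        genome = cb.generate_genome(cfg)
        rep = cluster_randomization_test(genome.trna_genes, n_rand=200, seed=1)
        assert rep.observed_mean_pct == pytest.approx(100.0)
        assert rep.empirical_p < 0.05 and rep.binomial_p < 1e-10

    def test_invariant_to_chromosome_names_and_order(self, rng):
        genes = [_gene(f"g{i}", "chr1", i * 3_000,
                       family=["G-GCC", "K-TTT"][i % 2]) for i in range(10)]
        renamed = [TrnaGene(g.gene_id, "chrX", g.start, g.end, g.strand,
                            g.anticodon, g.isotype) for g in genes]
        r1 = cluster_randomization_test(genes, n_rand=100, seed=0)
        r2 = cluster_randomization_test(renamed[::-1], n_rand=100, seed=0)
        assert r1.observed_mean_pct == r2.observed_mean_pct
        assert r1.n_colocalized == r2.n_colocalized

    def test_no_clusters_skips_with_warning(self, caplog):
        genes = [_gene(f"g{i}", "chr1", i * 50_000) for i in range(4)]
        with caplog.at_level("WARNING"):
            rep = cluster_randomization_test(genes, n_rand=10, seed=0)
        assert rep.skipped and rep.observed_mean_pct == 0.0


class TestCompensationVsClustering:
    def _results(self, sig_flags):
        out = []
        for i, sig in enumerate(sig_flags):
            out.append(cb.CompensationResult(
                family_id=f"f{i}", n_genes=6,
                observed_correlations=np.zeros(15),
                null_correlations=np.zeros(15), chi2_stat=0.0,
                p_raw=0.01 if sig else 0.9, p_corrected=0.01 if sig else 0.9,
                significant=sig, expression_clusters=None, bimodality=0.0))
        return out

    def test_identical_distributions_null(self):
        res = self._results([True] * 4 + [False] * 4)
        fracs = {f"f{i}": [10, 40, 60, 90][i % 4] for i in range(8)}
        chi2, p = compensation_vs_clustering(res, fracs)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_disjoint_distributions_significant(self):
        res = self._results([True] * 10 + [False] * 10)
        fracs = {f"f{i}": (0.0 if i < 10 else 100.0) for i in range(20)}
        _, p = compensation_vs_clustering(res, fracs)
        assert p < 0.01

    def test_one_group_empty_rejected(self):
        res = self._results([True, True, True])
        with pytest.raises(ValueError, match="each group"):
            compensation_vs_clustering(res, {f"f{i}": 50.0 for i in range(3)})
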