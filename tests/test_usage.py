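"""Codon counting, expression-weighted usage, abundance profiles, and the
interface correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import codonbalance as cb
from codonbalance.core import TrnaGene
from codonbalance.usage import codon_count_matrix


def _trna(gene_id, isotype, anticodon, chrom="chr1", start=0):
    return TrnaGene(gene_id, chrom, start, start + 72, "+", anticodon, isotype)


class TestCountCodons:
    @pytest.mark.parametrize("cds,expected", [
        ("ATGGCTTAA", {"ATG": 1, "GCT": 1, "TAA": 1}),
        ("AAAAAA", {"AAA": 2}),
        ("ATGATGATG", {"ATG": 3}),
    ])
    def test_enumeration(self, cds, expected):
        assert cb.count_codons(cds) == expected

    @pytest.mark.parametrize("cds", ["", "ATGA", "ATGGC"])
    def test_bad_length_rejected(self, cds):
        with pytest.raises(ValueError):
            cb.count_codons(cds)

    @given(st.integers(1, 60), st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_total_equals_codon_count(self, n_codons, seed):
        rng = np.random.default_rng(seed)
        cds = "".join(rng.choice(list("ACGT"), size=3 * n_codons))
        assert sum(cb.count_codons(cds).values()) == n_codons

    def test_matrix_agrees_with_per_gene(self, small_sim):
        _, genome, *_ = small_sim
        mat = codon_count_matrix(genome.transcripts[:10])
        for t in genome.transcripts[:10]:
            row = mat.loc[t.gene_id]
            assert {c: int(v) for c, v in row.items() if v} == cb.count_codons(t)


class TestWeightedUsage:
    def test_hand_enumeration_oracle(self):
        # g1 "AAAAAA" at weight 10/kb-equivalent, g2 "AAGAAGAAG" at weight 5
        tables = codon_count_matrix([cb.TranscriptRecord("g1", "AAAAAA"),
                                     cb.TranscriptRecord("g2", "AAGAAGAAG")])
        u = cb.weighted_usage(tables, {"g1": 10.0, "g2": 5.0},
                              lengths={"g1": 1000, "g2": 1000})
        assert u["AAA"] == pytest.approx(20.0)
        assert u["AAG"] == pytest.approx(15.0)

    def test_stop_codons_excluded(self):
        tables = codon_count_matrix([cb.TranscriptRecord("g1", "ATGTAA")])
        u = cb.weighted_usage(tables, {"g1": 1.0})
        assert "TAA" not in u.keys
        assert u["ATG"] > 0

    def test_amino_acid_level_aggregates_through_code(self):
        tables = codon_count_matrix([cb.TranscriptRecord("g1", "AAAAAGAAA")])
        u_c = cb.weighted_usage(tables, {"g1": 3.0})
        u_aa = cb.weighted_usage(tables, {"g1": 3.0}, level="amino_acid")
        assert u_aa["K"] == pytest.approx(u_c["AAA"] + u_c["AAG"])

    def test_missing_gene_listed(self):
        tables = codon_count_matrix([cb.TranscriptRecord("g1", "AAAAAA")])
        with pytest.raises(KeyError, match="g1"):
            cb.weighted_usage(tables, {"other": 1.0})

    def test_aa_profile_equals_aggregated_codon_profile(self, small_sim):
        """Conservation: the amino-acid profile is exactly the code-grouped
        codon profile, for arbitrary expression weights."""
        _, genome, mrna, _, _ = small_sim
        tables = codon_count_matrix(genome.transcripts)
        expr = cb.normalize_counts(mrna).sample_values("liver", "P4")
        code = cb.load_genetic_code()
        u_c = cb.weighted_usage(tables, expr).normalize().as_series()
        u_aa = cb.weighted_usage(tables, expr, level="amino_acid") \
            .normalize().as_series()
        agg = u_c.groupby([code.amino_acid(c) for c in u_c.index]).sum()
        pd.testing.assert_series_equal(u_aa, agg.sort_index(),
                                       check_names=False, atol=1e-12, rtol=0)

    def test_scale_invariance_of_relative_profiles(self, small_sim):
        _, genome, mrna, _, _ = small_sim
        tables = codon_count_matrix(genome.transcripts)
        expr = cb.normalize_counts(mrna).sample_values("liver", "P4")
        u1 = cb.weighted_usage(tables, expr).normalize()
        u2 = cb.weighted_usage(tables, 2.0 * expr).normalize()
        np.testing.assert_allclose(u1.values, u2.values, rtol=0, atol=1e-12)

    def test_equal_expression_recovers_genomic_frequency(self, small_sim):
        """With equal expression and equal lengths the weighted profile is
        exactly the genomic codon frequency of the CDS set."""
        _, genome, *_ = small_sim
        tables = codon_count_matrix(genome.transcripts)
        code = cb.load_genetic_code()
        u = cb.weighted_usage(tables, {g: 1.0 for g in tables.index},
                              lengths={g: 1000 for g in tables.index}).normalize()
        sense = [c for c in tables.columns if c in code.sense_codons]
        genomic = tables[sense].sum(axis=0) / tables[sense].to_numpy().sum()
        np.testing.assert_allclose(u.values, genomic.reindex(u.keys).to_numpy(),
                                   atol=1e-12)


class TestRelativeUsage:
    def test_normalization_examples(self):
        u = cb.UsageProfile(["AAA", "AAG"], [2.0, 2.0], "codon")
        assert list(cb.relative_usage(u).values) == [0.5, 0.5]
        s = cb.UsageProfile(["ATG"], [7.0], "codon")
        assert cb.relative_usage(s)["ATG"] == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            cb.relative_usage(cb.UsageProfile(["AAA"], [0.0], "codon"))


class TestAnticodonAbundance:
    def test_family_sums(self):
        genes = [_trna("t1", "G", "GCC"), _trna("t2", "G", "GCC", start=1000),
                 _trna("t3", "K", "TTT", start=2000)]
        prof = cb.anticodon_abundance({"t1": 3.0, "t2": 7.0, "t3": 10.0}, genes)
        assert prof["G-GCC"] == pytest.approx(0.5)
        assert prof["K-TTT"] == pytest.approx(0.5)

    def test_isotype_level(self):
        genes = [_trna("t1", "L", "CAG"), _trna("t2", "L", "AAG", start=1000)]
        prof = cb.anticodon_abundance({"t1": 2.0, "t2": 3.0}, genes,
                                      level="isotype")
        assert prof["L"] == pytest.approx(1.0)

    def test_selenocysteine_and_unknown_genes(self):
        genes = [_trna("t1", "G", "GCC"), _trna("sec", "SeC", "TCA", start=500)]
        with pytest.raises(KeyError, match="sec"):
            cb.anticodon_abundance({"t1": 1.0, "sec": 1.0}, genes)
        with pytest.raises(KeyError, match="ghost"):
            cb.anticodon_abundance({"ghost": 1.0}, genes)


class TestInterfaceCorrelation:
    def test_monotone_transform_gives_rho_one(self):
        code = cb.load_genetic_code()
        codons = sorted(code.sense_codons)[:10]
        vals = np.linspace(0.01, 0.2, 10)
        vals /= vals.sum()
        codon_u = cb.UsageProfile(codons, vals, "codon", normalized=True)
        fams = [f"{code.amino_acid(c)}-{cb.reverse_complement(c)}" for c in codons]
        anti = cb.UsageProfile(sorted(fams), np.array(
            [vals[fams.index(f)] ** 2 for f in sorted(fams)]) /
            sum(v ** 2 for v in vals), "anticodon", normalized=True)
        rho, p, n = cb.interface_correlation(codon_u, anti)
        assert rho == pytest.approx(1.0)
        assert n == 10

    def test_too_few_pairs_rejected(self):
        codon_u = cb.UsageProfile(["AAA"], [1.0], "codon", normalized=True)
        anti = cb.UsageProfile(["K-TTT"], [1.0], "anticodon", normalized=True)
        with pytest.raises(ValueError, match="4"):
            cb.interface_correlation(codon_u, anti)

    def test_independent_profiles_centered_at_zero(self, rng):
        code = cb.load_genetic_code()
        codons = sorted(code.sense_codons)[:57]
        fams = [f"{code.amino_acid(c)}-{cb.reverse_complement(c)}" for c in codons]
        rhos = []
        for _ in range(300):
            x = rng.random(57)
            y = rng.random(57)
            cu = cb.UsageProfile(codons, x / x.sum(), "codon", normalized=True)
            au = cb.UsageProfile(fams, y / y.sum(), "anticodon")
            rhos.append(cb.interface_correlation(cu, au)[0])
        assert abs(np.mean(rhos)) < 0.05

    def test_unencoded_codons_excluded(self):
        code = cb.load_genetic_code()
        codons = sorted(code.sense_codons)[:8]
        vals = np.full(8, 1 / 8)
        cu = cb.UsageProfile(codons, vals, "codon", normalized=True)
        fams = [f"{code.amino_acid(c)}-{cb.reverse_complement(c)}"
                for c in codons[:5]]
        au = cb.UsageProfile(fams, np.full(5, 0.2), "anticodon", normalized=True)
        _, _, n = cb.interface_correlation(cu, au, exclude_unencoded=True)
        assert n == 5


class TestPartitionByExpression:
    def test_decile_counts(self):
        expr = {f"g{i}": float(i) for i in range(10)}
        high, low = cb.partition_by_expression(expr)
        assert low == ["g0"] and high == ["g9"]

    def test_tie_break_by_gene_id(self):
        expr = {"b": 1.0, "a": 1.0, "c": 1.0, "d": 1.0, "e": 1.0}
        high, low = cb.partition_by_expression(expr, 0.2, 0.8)
        assert low == ["a"] and high == ["e"]

    def test_degenerate_quantiles_rejected(self):
        with pytest.raises(ValueError):
            cb.partition_by_expression({"a": 1.0, "b": 2.0}, 0.5, 0.5)
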