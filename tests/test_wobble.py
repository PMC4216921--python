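"""Wobble rules, orphan-codon assignment, and abundance redistribution."""

import numpy as np
import pytest

import codonbalance as cb
from codonbalance.core import UsageProfile, load_genetic_code, reverse_complement
from codonbalance.wobble import WobbleRuleTable


def _fam(codon, code=None):
    code = code or load_genetic_code()
    return f"{code.amino_acid(codon)}-{reverse_complement(codon)}"


class TestFindOrphans:
    def test_complete_catalogue_has_no_orphans(self, code):
        assert cb.find_orphan_codons(code, cb.all_watson_crick_families()) == set()

    def test_single_removed_family_orphans_its_codon(self, code):
        fams = [f for f in cb.all_watson_crick_families() if f != _fam("GGC")]
        assert cb.find_orphan_codons(code, fams) == {"GGC"}


class TestWobbleRules:
    def test_defaults_extend_watson_crick(self):
        rules = WobbleRuleTable()
        assert rules.reads("G", "C") and rules.reads("G", "T")
        assert rules.reads("A", "A")  # inosine
        assert not rules.reads("C", "A")

    def test_rule_missing_wc_base_rejected(self):
        with pytest.raises(ValueError, match="Watson-Crick"):
            WobbleRuleTable({"G": frozenset({"T"}), "T": frozenset({"A", "G"}),
                             "A": frozenset({"T"}), "C": frozenset({"G"})})


class TestAssignDecoders:
    def test_c_ending_orphan_goes_to_inosine_family(self, code):
        # orphan GGC (Gly, third base C): its absent Watson-Crick anticodon
        # is the G34 one, so the inosine-forming A34 family must serve it
        fams = [_fam(c) for c in code.sense_codons if c != "GGC"]
        dmap = cb.assign_wobble_decoders({"GGC"}, fams)
        assert dmap.codon_to_family["GGC"] == "G-ACC"

    def test_preference_order_with_extended_rules(self, code):
        # orphan GCC (Ala, ends C) with Ala-AGC and Ala-TGC both able to
        # read C under an extended rule table: A34 preferred over T34, and
        # T34 used once the A34 family is also absent
        rules = WobbleRuleTable({"G": frozenset({"C", "T"}),
                                 "T": frozenset({"A", "G", "C"}),
                                 "A": frozenset({"T", "C", "A"}),
                                 "C": frozenset({"G"})})
        fams = [_fam(c) for c in code.sense_codons if c != "GCC"]
        dmap = cb.assign_wobble_decoders({"GCC"}, fams, rules=rules)
        assert dmap.codon_to_family["GCC"] == "A-AGC"
        fams2 = [f for f in fams if f != "A-AGC"]
        dmap2 = cb.assign_wobble_decoders({"GCC", "GCT"}, fams2, rules=rules)
        assert dmap2.codon_to_family["GCC"] == "A-TGC"

    def test_g34_serves_t_ending_orphan(self, code):
        fams = [_fam(c) for c in code.sense_codons if c != "AAT"]
        dmap = cb.assign_wobble_decoders({"AAT"}, fams)
        assert dmap.codon_to_family["AAT"] == "N-GTT"

    def test_isotype_with_no_family_is_unmatchable(self, code):
        fams = [_fam(c) for c in code.sense_codons
                if code.amino_acid(c) != "W"]
        orphans = cb.find_orphan_codons(code, fams)
        dmap = cb.assign_wobble_decoders(orphans, fams)
        assert dmap.unmatchable == {"TGG"}

    def test_assignments_never_cross_isotypes(self, code):
        cat = cb.default_encoded_families()
        dmap = cb.assign_wobble_decoders(cb.find_orphan_codons(code, cat), cat)
        for codon, fam in dmap.codon_to_family.items():
            assert fam.split("-")[0] == code.amino_acid(codon)


class TestRedistribute:
    def test_proportional_split(self):
        fam = UsageProfile(["A-AGC"], [10.0], "anticodon")
        dmap = cb.DecodingMap({"A-AGC": ["GCT", "GCC"]},
                              {"GCT": "A-AGC", "GCC": "A-AGC"})
        demand = UsageProfile(["GCT", "GCC"], [0.75, 0.25], "codon",
                              normalized=True)
        avail = cb.redistribute_abundance(fam, dmap, demand)
        assert avail["GCT"] == pytest.approx(7.5)
        assert avail["GCC"] == pytest.approx(2.5)

    def test_single_codon_identity_and_zero_demand_split(self):
        fam = UsageProfile(["A-AGC", "K-TTT"], [4.0, 6.0], "anticodon")
        dmap = cb.DecodingMap({"A-AGC": ["GCT"], "K-TTT": ["AAA", "AAG"]},
                              {"GCT": "A-AGC", "AAA": "K-TTT", "AAG": "K-TTT"})
        demand = UsageProfile(["GCT", "AAA", "AAG"], [1.0, 0.0, 0.0], "codon")
        avail = cb.redistribute_abundance(fam, dmap, demand)
        assert avail["GCT"] == pytest.approx(4.0)
        assert avail["AAA"] == pytest.approx(3.0)  # equal split of 6.0
        assert avail["AAG"] == pytest.approx(3.0)

    def test_conservation_on_random_family_sets(self, code, rng):
        allfam = cb.all_watson_crick_families()
        codons = sorted(code.sense_codons)
        for _ in range(200):
            k = int(rng.integers(20, 62))
            fams = sorted(rng.choice(allfam, size=k, replace=False))
            a = rng.random(k)
            fam_prof = UsageProfile(fams, a, "anticodon")
            d = rng.random(61)
            demand = UsageProfile(codons, d / d.sum(), "codon", normalized=True)
            dmap = cb.assign_wobble_decoders(
                cb.find_orphan_codons(code, fams), fams)
            avail = cb.redistribute_abundance(fam_prof, dmap, demand)
            mapped = set(dmap.family_to_codons)
            total = sum(v for f, v in zip(fams, a) if f in mapped)
            assert abs(avail.values.sum() - total) < 1e-9

    def test_family_serving_nothing_rejected(self):
        fam = UsageProfile(["A-AGC"], [1.0], "anticodon")
        dmap = cb.DecodingMap({"A-AGC": []}, {})
        demand = UsageProfile(["GCT"], [1.0], "codon")
        with pytest.raises(ValueError, match="serves no codon"):
            cb.redistribute_abundance(fam, dmap, demand)


class TestCorrectedCorrelation:
    def test_no_orphans_equals_uncorrected_exactly(self, code, rng):
        fams = cb.all_watson_crick_families()
        codons = sorted(code.sense_codons)
        d = rng.random(61)
        demand = UsageProfile(codons, d / d.sum(), "codon", normalized=True)
        a = rng.random(61)
        fam_prof = UsageProfile(fams, a / a.sum(), "anticodon", normalized=True)
        rho_u, _, n_u = cb.interface_correlation(demand, fam_prof)
        rho_c, _, n_c = cb.wobble_corrected_correlation(demand, fam_prof)
        assert rho_c == rho_u
        assert n_c == n_u == 61

    def test_correction_stays_near_uncorrected_on_encoded_catalogue(
            self, code, rng):
        """The wobble correction shifts, but does not destroy, the interface
        correlation on family sets with the standard 15 orphans."""
        cat = cb.default_encoded_families()
        codons = sorted(code.sense_codons)
        diffs = []
        for _ in range(30):
            x = np.sort(rng.random(61))
            demand = UsageProfile(codons, x / x.sum(), "codon", normalized=True)
            # abundance rank-coupled to demand of the matching codon
            vals = {}
            for f in cat:
                c = reverse_complement(f.rpartition("-")[2])
                vals[f] = demand[c] * rng.lognormal(0, 0.4)
            a = np.array([vals[f] for f in cat])
            fam_prof = UsageProfile(cat, a / a.sum(), "anticodon",
                                    normalized=True)
            rho_u = cb.interface_correlation(demand, fam_prof)[0]
            rho_c = cb.wobble_corrected_correlation(demand, fam_prof)[0]
            diffs.append(rho_c - rho_u)
            assert rho_c > 0
        assert -0.2 <= float(np.mean(diffs)) <= 0.05
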