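"""Orphan-codon identification and demand-weighted redistribution of
wobbling isoacceptor abundance onto codons.

A sense codon is an *orphan* when no gene with its exact Watson-Crick
anticodon is genomically encoded. Such codons are decoded via wobble pairing
at codon position 3 / anticodon position 34 by a closely related isoacceptor
of the same isotype. The default rule table is the classic wobble set plus
inosine: G34 reads C/T, T34 reads A/G, A34 (deaminated to inosine) reads
T/C/A, and C34 reads only G.

After assignment, each family's abundance is split over the codons it serves
proportionally to codon demand, so the total availability over codons equals
the total abundance over mapped families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import GeneticCode, UsageProfile, load_genetic_code, reverse_complement

logger = logging.getLogger("codonbalance")

#: deterministic preference order over candidate wobble bases
WOBBLE_PREFERENCE = ("G", "A", "T", "C")

_WC_PARTNER = {"G": "C", "T": "A", "A": "T", "C": "G"}


@dataclass(frozen=True)
class WobbleRuleTable:
    """Map anticodon wobble base (position 34) -> codon third-position bases
    it can read. Rules only ever extend the Watson-Crick pairing."""

    rules: Mapping[str, frozenset[str]] = field(default_factory=lambda: {
        "G": frozenset({"C", "T"}),
        "T": frozenset({"A", "G"}),
        "A": frozenset({"T", "C", "A"}),  # inosine
        "C": frozenset({"G"}),
    })

    def __post_init__(self) -> None:
        for base, reads in self.rules.items():
            if _WC_PARTNER[base] not in reads:
                raise ValueError(f"wobble rule for {base}34 must include its "
                                 f"Watson-Crick codon base {_WC_PARTNER[base]}")

    def reads(self, wobble_base: str, codon_third: str) -> bool:
        return codon_third in self.rules.get(wobble_base, frozenset())


@dataclass
class DecodingMap:
    """Which anticodon family serves which codons (Watson-Crick + orphans)."""

    family_to_codons: dict[str, list[str]]
    codon_to_family: dict[str, str]
    unmatchable: set[str] = field(default_factory=set)


def _family_anticodon(family_id: str) -> tuple[str, str]:
    isotype, _, anticodon = family_id.rpartition("-")
    return isotype, anticodon


def find_orphan_codons(code: GeneticCode | None,
                       encoded_families: Sequence[str] | set[str]) -> set[str]:
    """Sense codons whose Watson-Crick anticodon is absent from the encoded
    family set."""
    code = code or load_genetic_code()
    encoded_anticodons = {_family_anticodon(f)[1] for f in encoded_families}
    return {c for c in code.sense_codons
            if reverse_complement(c) not in encoded_anticodons}


def assign_wobble_decoders(
    orphans: set[str] | Sequence[str],
    encoded_families: Sequence[str],
    rules: WobbleRuleTable | None = None,
    code: GeneticCode | None = None,
) -> DecodingMap:
    """Assign each orphan codon to a same-isotype wobble decoder.

    Candidates must differ from the orphan's Watson-Crick anticodon only at
    position 34 and be able to read the orphan's third base under ``rules``;
    ties are broken by the fixed wobble-base preference G34 > A34 > T34 >
    C34. Orphans with no candidate are recorded as unmatchable.
    """
    rules = rules or WobbleRuleTable()
    code = code or load_genetic_code()
    fam_by_anticodon: dict[str, str] = {}
    for f in encoded_families:
        fam_by_anticodon[_family_anticodon(f)[1]] = f

    family_to_codons: dict[str, list[str]] = {}
    codon_to_family: dict[str, str] = {}
    for c in sorted(code.sense_codons):
        f = fam_by_anticodon.get(reverse_complement(c))
        if f is not None:
            family_to_codons.setdefault(f, []).append(c)
            codon_to_family[c] = f

    unmatchable: set[str] = set()
    for orphan in sorted(orphans):
        wc = reverse_complement(orphan)  # absent anticodon
        assigned = None
        for base in WOBBLE_PREFERENCE:
            candidate_anticodon = base + wc[1:]
            f = fam_by_anticodon.get(candidate_anticodon)
            if f is None:
                continue
            isotype, _ = _family_anticodon(f)
            if isotype != code.amino_acid(orphan):  # never cross isotypes
                continue
            if rules.reads(base, orphan[2]):
                assigned = f
                break
        if assigned is None:
            unmatchable.add(orphan)
        else:
            family_to_codons.setdefault(assigned, []).append(orphan)
            codon_to_family[orphan] = assigned
    if unmatchable:
        logger.warning("assign_wobble_decoders: %d unmatchable orphan codons: %s",
                       len(unmatchable), sorted(unmatchable))
    return DecodingMap(family_to_codons, codon_to_family, unmatchable)


def redistribute_abundance(
    family_abundance: UsageProfile,
    dmap: DecodingMap,
    codon_demand: UsageProfile,
) -> UsageProfile:
    """Split each family's abundance over the codons it serves,
    proportionally to codon demand (equal split when all demands are zero).

    The returned per-codon availability conserves the total abundance of the
    mapped families exactly.
    """
    abundance = dict(zip(family_abundance.keys, family_abundance.values))
    demand = dict(zip(codon_demand.keys, codon_demand.values))
    availability: dict[str, float] = {}
    for family, codons in dmap.family_to_codons.items():
        if not codons:
            raise ValueError(f"family {family} serves no codon")
        if family not in abundance:
            raise KeyError(f"family {family} missing from abundance profile")
        a = abundance[family]
        weights = np.array([demand.get(c, 0.0) for c in codons], dtype=float)
        total = weights.sum()
        if total <= 0:
            weights = np.full(len(codons), 1.0 / len(codons))
        else:
            weights = weights / total
        for c, w in zip(codons, weights):
            availability[c] = availability.get(c, 0.0) + a * w
    keys = sorted(availability)
    return UsageProfile(keys, np.array([availability[k] for k in keys]),
                        kind="codon", normalized=False)


def wobble_corrected_correlation(
    codon_demand: UsageProfile,
    family_abundance: UsageProfile,
    rules: WobbleRuleTable | None = None,
    code: GeneticCode | None = None,
) -> tuple[float, float, int]:
    """Spearman correlation between codon demand and wobble-corrected
    per-codon tRNA availability.

    Unmatchable orphan codons are excluded; with zero orphans the result
    equals the uncorrected interface correlation exactly.
    """
    from scipy import stats

    code = code or load_genetic_code()
    orphans = find_orphan_codons(code, family_abundance.keys)
    dmap = assign_wobble_decoders(orphans, family_abundance.keys, rules, code)
    availability = redistribute_abundance(family_abundance, dmap, codon_demand)
    avail = dict(zip(availability.keys, availability.values))
    x, y = [], []
    for codon, value in zip(codon_demand.keys, codon_demand.values):
        if codon in dmap.codon_to_family:
            x.append(value)
            y.append(avail[codon])
    if len(x) < 4:
        raise ValueError(f"only {len(x)} served codons; need >= 4")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), len(x)
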