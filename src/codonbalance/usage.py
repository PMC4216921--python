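"""Expression-weighted codon and amino-acid usage, tRNA isoacceptor and
isotype abundance, and the codon-anticodon interface correlation.

The central quantity is the usage of key ``k`` (a codon or amino acid) in one
library:

    U_k = sum_g  n_{g,k} * e_g / (L_g / 1000)

where ``n_{g,k}`` is the number of occurrences of ``k`` in gene ``g``'s
longest CDS, ``e_g`` its library-size-normalized expression, and ``L_g`` the
CDS length in nucleotides (expression per kilobase of counted sequence).
Relative usage is the simple normalization u_k = U_k / sum_j U_j.

On the tRNA side, isoacceptor family abundance sums normalized Pol III
occupancy over the family's member genes; isotype abundance further sums
families by amino acid. The interface correlation is the Spearman rank
correlation between relative codon usage and the relative abundance of each
codon's Watson-Crick anticodon family, excluding codons whose anticodon is
not genomically encoded.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GeneticCode,
    TranscriptRecord,
    TrnaGene,
    UsageProfile,
    load_genetic_code,
    make_family_id,
    reverse_complement,
)

ALL_CODONS = sorted(load_genetic_code().table)
SENSE_CODONS = sorted(load_genetic_code().sense_codons)
_CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
_POWERS = np.array([16, 4, 1], dtype=np.int64)
# ALL_CODONS is sorted, so the base-4 code of a codon IS its index.
assert all(_CODON_INDEX[c] == 16 * _BASE_CODE[ord(c[0])] + 4 * _BASE_CODE[ord(c[1])]
           + _BASE_CODE[ord(c[2])] for c in ALL_CODONS)


def count_codons(transcript: TranscriptRecord | str) -> dict[str, int]:
    """In-frame, non-overlapping codon counts for one CDS.

    Stop codons are included in the raw table; downstream profile builders
    restrict to sense codons.
    """
    cds = transcript.cds if isinstance(transcript, TranscriptRecord) else transcript
    if len(cds) == 0 or len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is empty or not divisible by 3")
    codes = _BASE_CODE[np.frombuffer(cds.encode(), dtype=np.uint8)]
    if np.any(codes < 0):
        raise ValueError("CDS contains non-ACGT characters")
    idx = codes.reshape(-1, 3) @ _POWERS
    counts = np.bincount(idx, minlength=64)
    return {ALL_CODONS[i]: int(counts[i]) for i in np.nonzero(counts)[0]}


def codon_count_matrix(transcripts: Sequence[TranscriptRecord]) -> pd.DataFrame:
    """Genes x 64 codon-count matrix (the bulk form of :func:`count_codons`)."""
    mat = np.zeros((len(transcripts), 64), dtype=np.int64)
    for i, t in enumerate(transcripts):
        codes = _BASE_CODE[np.frombuffer(t.cds.encode(), dtype=np.uint8)]
        idx = codes.reshape(-1, 3) @ _POWERS
        mat[i] = np.bincount(idx, minlength=64)
    return pd.DataFrame(mat, index=pd.Index([t.gene_id for t in transcripts],
                                            name="gene_id"), columns=ALL_CODONS)


def weighted_usage(
    tables: pd.DataFrame,
    expr: Mapping[str, float] | pd.Series,
    lengths: Mapping[str, int] | pd.Series | None = None,
    level: str = "codon",
    code: GeneticCode | None = None,
) -> UsageProfile:
    """Expression-weighted (unnormalized) codon or amino-acid usage.

    Each gene's codon counts are multiplied by its expression per kilobase of
    the counted CDS, then summed across genes. Stop codons are excluded here;
    amino-acid level aggregates codon values through the genetic code.

    Parameters
    ----------
    tables : genes x codons count matrix (from :func:`codon_count_matrix`).
    expr : per-gene library-size-normalized expression.
    lengths : per-gene length in nt of the counted transcript; defaults to
        3 x the row sum of ``tables`` (the CDS itself).
    """
    if level not in {"codon", "amino_acid"}:
        raise ValueError("level must be 'codon' or 'amino_acid'")
    code = code or load_genetic_code()
    expr = pd.Series(expr)
    missing = tables.index.difference(expr.index)
    if len(missing):
        raise KeyError(f"genes missing from expression: {sorted(missing)[:10]}"
                       f"{'...' if len(missing) > 10 else ''}")
    expr = expr.reindex(tables.index)
    if lengths is None:
        lengths = 3.0 * tables.sum(axis=1)
    else:
        lengths = pd.Series(lengths).reindex(tables.index)
        if lengths.isna().any():
            raise KeyError("genes missing from lengths")
    weights = expr.to_numpy(dtype=float) / (lengths.to_numpy(dtype=float) / 1000.0)
    sense = [c for c in tables.columns if c in code.sense_codons]
    u = pd.Series(weights @ tables[sense].to_numpy(dtype=float), index=sense)
    if level == "amino_acid":
        u = u.groupby([code.amino_acid(c) for c in u.index]).sum().sort_index()
    return UsageProfile(list(u.index), u.to_numpy(), kind=level, normalized=False)


def relative_usage(profile: UsageProfile) -> UsageProfile:
    """u_i = U_i / sum_j U_j; errors on a zero total."""
    return profile.normalize()


def anticodon_abundance(
    trna_expr: Mapping[str, float] | pd.Series,
    genes: Sequence[TrnaGene],
    level: str = "anticodon",
) -> UsageProfile:
    """Relative isoacceptor-family (or isotype) abundance.

    Family abundance sums the normalized expression of the family's member
    genes; the profile is then normalized. Selenocysteine genes are excluded.
    """
    if level not in {"anticodon", "isotype"}:
        raise ValueError("level must be 'anticodon' or 'isotype'")
    trna_expr = pd.Series(trna_expr)
    by_gene = {g.gene_id: g for g in genes if not g.is_selenocysteine}
    unknown = [gid for gid in trna_expr.index if gid not in by_gene]
    if unknown:
        raise KeyError(f"tRNA genes with unknown family: {unknown[:10]}")
    totals: dict[str, float] = {}
    for gid, value in trna_expr.items():
        g = by_gene[gid]
        key = g.family_id if level == "anticodon" else g.isotype
        totals[key] = totals.get(key, 0.0) + float(value)
    keys = sorted(totals)
    prof = UsageProfile(keys, np.array([totals[k] for k in keys]), kind=level)
    return prof.normalize()


def watson_crick_pairing(
    codon_keys: Sequence[str], family_ids: Sequence[str],
    code: GeneticCode | None = None,
) -> dict[str, str]:
    """Map each codon to its Watson-Crick anticodon family, where encoded.

    Family ids are ``isotype-anticodon``; a codon pairs with the family whose
    anticodon is the codon's reverse complement and whose isotype matches the
    codon's amino acid.
    """
    code = code or load_genetic_code()
    by_anticodon: dict[str, str] = {}
    for fid in family_ids:
        isotype, _, anticodon = fid.rpartition("-")
        by_anticodon[anticodon] = fid
    pairing: dict[str, str] = {}
    for c in codon_keys:
        fid = by_anticodon.get(reverse_complement(c))
        if fid is not None:
            pairing[c] = fid
    return pairing


def interface_correlation(
    codon_u: UsageProfile,
    anticodon_u: UsageProfile,
    pairing: Mapping[str, str] | None = None,
    exclude_unencoded: bool = True,
) -> tuple[float, float, int]:
    """Spearman correlation between codon demand and anticodon availability.

    Pairs each codon with its (Watson-Crick, unless ``pairing`` overrides)
    anticodon family and correlates the two relative profiles over codons.
    Codons whose anticodon family is not genomically encoded are excluded
    when ``exclude_unencoded`` (otherwise they enter with abundance 0).

    Returns ``(rho, p, n_pairs)``.
    """
    fam = dict(zip(anticodon_u.keys, anticodon_u.values))
    if pairing is None:
        pairing = watson_crick_pairing(codon_u.keys, anticodon_u.keys)
    x, y = [], []
    for codon, value in zip(codon_u.keys, codon_u.values):
        fid = pairing.get(codon)
        if fid is None or fid not in fam:
            if exclude_unencoded:
                continue
            x.append(value)
            y.append(0.0)
        else:
            x.append(value)
            y.append(fam[fid])
    if len(x) < 4:
        raise ValueError(f"only {len(x)} codon/anticodon pairs; need >= 4")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), len(x)


def partition_by_expression(
    expr: Mapping[str, float] | pd.Series,
    q_low: float = 0.1,
    q_high: float = 0.9,
) -> tuple[list[str], list[str]]:
    """Deterministic (high, low) quantile split of genes by expression.

    The bottom ``round(n*q_low)`` genes form the low set and the top
    ``round(n*(1-q_high))`` the high set; ties are broken by gene_id order.
    """
    if not 0 <= q_low < q_high <= 1:
        raise ValueError("require 0 <= q_low < q_high <= 1")
    expr = pd.Series(expr)
    order = sorted(expr.index, key=lambda g: (expr[g], g))
    n = len(order)
    n_low = int(round(n * q_low))
    n_high = int(round(n * (1.0 - q_high)))
    if n_low == 0 or n_high == 0 or n_low + n_high > n:
        raise ValueError(f"empty or overlapping partitions (n={n}, "
                         f"n_low={n_low}, n_high={n_high})")
    return order[n - n_high:], order[:n_low]
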