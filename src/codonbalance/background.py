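"""Shuffled-transcriptome background distributions.

Artificial transcriptomes are created by permuting the observed expression
values across genes — either across the expressed gene set only, or across
all annotated genes (the observed value multiset padded with zeros up to the
universe size, then permuted). For each of ``n_reps`` shuffles the codon /
amino-acid usage and anticodon / isotype abundance profiles are recomputed,
and the interface correlation between shuffled mRNA replicate i and shuffled
tRNA replicate i is recorded (a crossed all-pairs mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import TrnaGene, UsageProfile
from .usage import (
    anticodon_abundance,
    interface_correlation,
    weighted_usage,
)

UNIVERSES = ("expressed", "all_annotated")


def shuffle_expression(
    expr: Mapping[str, float] | pd.Series,
    universe: str = "expressed",
    genes_all: Sequence[str] | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.Series:
    """Randomly reassign expression values across genes.

    ``expressed`` mode permutes the values among the observed genes; the
    value multiset is preserved exactly. ``all_annotated`` mode pads the
    multiset with zeros up to ``len(genes_all)`` and permutes over that
    universe.
    """
    if universe not in UNIVERSES:
        raise ValueError(f"universe must be one of {UNIVERSES}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    expr = pd.Series(expr)
    if universe == "expressed":
        values = expr.to_numpy(copy=True)
        rng.shuffle(values)
        return pd.Series(values, index=expr.index)
    if genes_all is None:
        raise ValueError("all_annotated mode requires genes_all")
    if len(genes_all) < len(expr):
        raise ValueError(f"universe ({len(genes_all)}) smaller than the "
                         f"expression vector ({len(expr)})")
    values = np.zeros(len(genes_all))
    values[: len(expr)] = expr.to_numpy()
    rng.shuffle(values)
    return pd.Series(values, index=list(genes_all))


@dataclass
class BackgroundSummary:
    """Mean shuffled profiles and the per-replicate interface correlations."""

    mean_profiles: dict[str, UsageProfile]  # kind -> mean relative profile
    correlations: np.ndarray                # per replicate (or pair) rho
    n_reps: int
    universe: str


def background_distributions(
    codon_tables: pd.DataFrame,
    mrna_expr: pd.Series,
    trna_expr: pd.Series,
    trna_genes: Sequence[TrnaGene],
    universe: str = "expressed",
    mrna_genes_all: Sequence[str] | None = None,
    trna_genes_all: Sequence[TrnaGene] | None = None,
    n_reps: int = 100,
    seed: int | None = 0,
    crossed: bool = False,
) -> BackgroundSummary:
    """Recompute usage/abundance profiles on ``n_reps`` shuffled
    transcriptomes and summarize them.

    Returns the per-key mean relative profiles over replicates for all four
    profile kinds and the interface correlations between shuffled mRNA and
    shuffled tRNA replicates (paired i-i by default; all n x n pairs when
    ``crossed``).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    if universe == "all_annotated":
        if mrna_genes_all is None or trna_genes_all is None:
            raise ValueError("all_annotated mode requires the annotated gene "
                             "universes for both mRNA and tRNA")
        table_universe = codon_tables.reindex(mrna_genes_all)
        if table_universe.isna().any().any():
            raise ValueError("codon_tables must cover all annotated genes")
        genes_for_abundance = list(trna_genes_all)
    else:
        table_universe = codon_tables.loc[list(mrna_expr.index)]
        genes_for_abundance = list(trna_genes)

    sums: dict[str, pd.Series] = {}
    codon_profiles: list[UsageProfile] = []
    anticodon_profiles: list[UsageProfile] = []
    for _ in range(n_reps):
        sh_mrna = shuffle_expression(mrna_expr, universe,
                                     genes_all=list(table_universe.index), rng=rng)
        if universe == "all_annotated":
            sh_trna = shuffle_expression(
                trna_expr, universe,
                genes_all=[g.gene_id for g in trna_genes_all], rng=rng)
        else:
            sh_trna = shuffle_expression(trna_expr, universe, rng=rng)
        profiles = {
            "codon": weighted_usage(table_universe, sh_mrna, level="codon").normalize(),
            "amino_acid": weighted_usage(table_universe, sh_mrna,
                                         level="amino_acid").normalize(),
            "anticodon": anticodon_abundance(sh_trna, genes_for_abundance,
                                             level="anticodon"),
            "isotype": anticodon_abundance(sh_trna, genes_for_abundance,
                                           level="isotype"),
        }
        codon_profiles.append(profiles["codon"])
        anticodon_profiles.append(profiles["anticodon"])
        for kind, prof in profiles.items():
            s = prof.as_series()
            sums[kind] = s if kind not in sums else sums[kind].add(s, fill_value=0.0)

    mean_profiles = {
        kind: UsageProfile(list(s.index), s.to_numpy() / n_reps, kind=kind)
        for kind, s in sums.items()
    }
    if crossed:
        rhos = [interface_correlation(cp, ap)[0]
                for cp in codon_profiles for ap in anticodon_profiles]
    else:
        rhos = [interface_correlation(cp, ap)[0]
                for cp, ap in zip(codon_profiles, anticodon_profiles)]
    return BackgroundSummary(mean_profiles, np.asarray(rhos), n_reps, universe)


@dataclass
class BackgroundComparison:
    observed_rho: float
    background_max: float
    background_mean: float
    background_sd: float
    exceedance: float  # (#background >= observed + 1) / (n + 1)
    n_background: int


def compare_observed_to_background(
    observed_rho: float, background_rhos: np.ndarray | Sequence[float],
) -> BackgroundComparison:
    """Empirical exceedance of the observed interface correlation over the
    shuffled-background correlations."""
    bg = np.asarray(background_rhos, dtype=float)
    if bg.size == 0:
        raise ValueError("empty background")
    exceed = (np.sum(bg >= observed_rho) + 1.0) / (bg.size + 1.0)
    return BackgroundComparison(
        observed_rho=float(observed_rho),
        background_max=float(bg.max()),
        background_mean=float(bg.mean()),
        background_sd=float(bg.std(ddof=1)) if bg.size > 1 else 0.0,
        exceedance=float(exceed),
        n_background=int(bg.size),
    )
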