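"""Within-family compensation statistics and genomic clustering of tRNA
genes.

Compensation test: for one isoacceptor family, all pairwise Spearman
correlations of member-gene expression across ordered developmental stages
are compared (chi-square goodness of fit on shared bins) against a null set
built by recomputing each pair's correlation under permuted stage orders.
Only the relative ordering of the two genes' stages matters for a rank
correlation, so the null enumerates the S! permutations of one gene's stages
(all of them when S! is below a cap, a seeded sample otherwise). A
significant departure — in practice a bimodal correlation distribution —
indicates two anti-correlated expression clusters whose family total stays
stable ("compensation").

Genomic clusters chain tRNA genes on one chromosome whose intergenic gaps
are at most ``gap_kb``; a family-label randomization test asks whether genes
of the same family colocalize in clusters more than chance expects.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import TrnaGene

logger = logging.getLogger("codonbalance")


class FamilySkipped(ValueError):
    """Raised when a family cannot be tested (too few usable genes)."""


# ---------------------------------------------------------------------------
# Compensation permutation test
# ---------------------------------------------------------------------------

@dataclass
class CompensationResult:
    family_id: str
    n_genes: int
    observed_correlations: np.ndarray
    null_correlations: np.ndarray
    chi2_stat: float
    p_raw: float
    p_corrected: float  # NaN until a screen applies a correction
    significant: bool
    expression_clusters: tuple[tuple[str, ...], tuple[str, ...]] | None
    bimodality: float  # descriptive |mean sign split| score, not the decision rule


def _merge_bins(observed: np.ndarray, expected: np.ndarray,
                min_expected: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate adjacent bins left to right until each group's expected
    count reaches the minimum; a trailing short group is merged into the
    previous one. Deterministic and order-preserving, so the tails of the
    correlation distribution stay separated from the center."""
    obs_groups: list[float] = []
    exp_groups: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(observed.astype(float), expected.astype(float)):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_groups.append(acc_o)
            exp_groups.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:
        if exp_groups:
            obs_groups[-1] += acc_o
            exp_groups[-1] += acc_e
        else:
            obs_groups, exp_groups = [acc_o], [acc_e]
    return np.asarray(obs_groups), np.asarray(exp_groups)


def _pairwise_rank_correlations(ranks: np.ndarray) -> np.ndarray:
    """Upper-triangle Pearson correlations of pre-ranked rows (= Spearman)."""
    z = ranks - ranks.mean(axis=1, keepdims=True)
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    corr = z @ z.T
    iu = np.triu_indices(len(ranks), k=1)
    return corr[iu]


def compensation_test(
    family_expr: pd.DataFrame,
    family_id: str = "",
    n_perm_cap: int = 720,
    bins: int = 20,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> CompensationResult:
    """Chi-square test of the observed pairwise-correlation distribution
    against its stage-permutation null for one family.

    ``family_expr``: genes x stages replicate-mean expression, columns in
    stage order. Genes with constant trajectories are excluded with a
    warning; fewer than 3 usable genes raises :class:`FamilySkipped`.
    """
    expr = family_expr.to_numpy(dtype=float)
    n_stages = expr.shape[1]
    if n_stages < 4:
        raise ValueError("need >= 4 stages for the compensation test")
    constant = np.ptp(expr, axis=1) == 0
    if constant.any():
        dropped = list(family_expr.index[constant])
        logger.warning("compensation_test(%s): dropping constant gene(s) %s",
                       family_id, dropped)
        family_expr = family_expr.loc[~constant]
        expr = expr[~constant]
    n_genes = expr.shape[0]
    if n_genes < 3:
        raise FamilySkipped(
            f"family {family_id!r}: {n_genes} usable genes (< 3)")

    ranks = np.apply_along_axis(stats.rankdata, 1, expr)
    observed = _pairwise_rank_correlations(ranks)

    # null: pairwise correlations under permuted relative stage orderings
    n_all = math.factorial(n_stages)
    if n_all <= n_perm_cap:
        perms = np.array(list(itertools.permutations(range(n_stages))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n_stages) for _ in range(n_perm_cap)])
    z = ranks - ranks.mean(axis=1, keepdims=True)
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    zp = z[:, perms]                      # genes x P x S
    null_all = np.einsum("gs,hps->ghp", z, zp)
    iu = np.triu_indices(n_genes, k=1)
    null = null_all[iu].ravel()

    edges = np.linspace(-1.0, 1.0, bins + 1)
    obs_counts, _ = np.histogram(np.clip(observed, -1.0, 1.0), bins=edges)
    null_counts, _ = np.histogram(np.clip(null, -1.0, 1.0), bins=edges)
    expected = null_counts / null_counts.sum() * len(observed)
    obs_m, exp_m = _merge_bins(obs_counts, expected)
    exp_m *= obs_m.sum() / exp_m.sum()  # guard against rounding drift
    if len(obs_m) < 2:
        chi2, p_raw = 0.0, 1.0
    else:
        chi2 = float(np.sum((obs_m - exp_m) ** 2 / exp_m))
        p_raw = float(stats.chi2.sf(chi2, df=len(obs_m) - 1))

    significant = p_raw < alpha
    clusters = None
    if significant and n_genes >= 2:
        corr_mat = np.corrcoef(ranks)
        w, v = np.linalg.eigh(corr_mat)
        lead = v[:, np.argmax(w)]
        pos = lead >= 0
        genes = list(family_expr.index)
        clusters = (tuple(g for g, f in zip(genes, pos) if f),
                    tuple(g for g, f in zip(genes, pos) if not f))
    bimodality = float(np.abs(np.sign(observed)).mean()
                       - np.abs(np.mean(np.sign(observed))))
    return CompensationResult(
        family_id=family_id, n_genes=n_genes,
        observed_correlations=observed, null_correlations=null,
        chi2_stat=chi2, p_raw=p_raw, p_corrected=float("nan"),
        significant=significant, expression_clusters=clusters,
        bimodality=bimodality,
    )


@dataclass
class CompensationScreen:
    reported: list[CompensationResult]        # families >= min_genes_report, corrected
    tested_small: list[CompensationResult]    # tested (>2 genes) but below report cutoff
    skipped: dict[str, str]                   # family -> reason


def compensation_screen(
    families: Mapping[str, pd.DataFrame],
    min_genes_report: int = 6,
    correction: str = "bonferroni",
    alpha: float = 0.05,
    n_perm_cap: int = 720,
    bins: int = 20,
    seed: int | None = 0,
) -> CompensationScreen:
    """Run the compensation test over all families with more than two genes
    and apply a multiplicity correction across the families large enough to
    report (>= ``min_genes_report`` genes)."""
    if correction not in {"bonferroni", "bh"}:
        raise ValueError("correction must be 'bonferroni' or 'bh'")
    reported: list[CompensationResult] = []
    tested_small: list[CompensationResult] = []
    skipped: dict[str, str] = {}
    for fam in sorted(families):
        try:
            res = compensation_test(families[fam], family_id=fam,
                                    n_perm_cap=n_perm_cap, bins=bins,
                                    alpha=alpha, seed=seed)
        except FamilySkipped as exc:
            skipped[fam] = str(exc)
            continue
        (reported if res.n_genes >= min_genes_report else tested_small).append(res)
    m = len(reported)
    if m == 0:
        logger.warning("compensation_screen: no families with >= %d genes",
                       min_genes_report)
        return CompensationScreen(reported, tested_small, skipped)
    if correction == "bonferroni":
        for r in reported:
            r.p_corrected = min(1.0, m * r.p_raw)
    else:
        from statsmodels.stats.multitest import multipletests
        _, adj, *_ = multipletests([r.p_raw for r in reported], method="fdr_bh")
        for r, a in zip(reported, adj):
            r.p_corrected = float(a)
    for r in reported:
        r.significant = r.p_corrected < alpha
    return CompensationScreen(reported, tested_small, skipped)


# ---------------------------------------------------------------------------
# Genomic clusters
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    clusters: list[list[str]]
    gap_kb: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, int]:
        return {g: i for i, cl in enumerate(self.clusters) for g in cl}


def define_clusters(genes: Sequence[TrnaGene], gap_kb: float = 7.5) -> ClusterSet:
    """Chain genes on one chromosome whose end-to-start gaps are <= gap_kb;
    maximal chains of >= 2 genes become clusters. Strand is ignored."""
    gap_nt = gap_kb * 1000.0
    by_chrom: dict[str, list[TrnaGene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    clusters: list[list[str]] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.gene_id))
        chain = [ordered[0]]
        for g in ordered[1:]:
            if g.start - chain[-1].end <= gap_nt:
                chain.append(g)
            else:
                if len(chain) >= 2:
                    clusters.append([x.gene_id for x in chain])
                chain = [g]
        if len(chain) >= 2:
            clusters.append([x.gene_id for x in chain])
    return ClusterSet(clusters, gap_kb)


@dataclass
class ClusterRandomizationReport:
    observed_mean_pct: float     # mean over families of % members colocalizing
    null_mean_pct: float
    null_pcts: np.ndarray
    empirical_p: float
    binomial_p: float
    n_colocalized: int
    n_genes: int
    family_fractions: pd.Series  # per-family % of members colocalized
    skipped: bool = False


def _colocalized_mask(cluster_idx: np.ndarray, labels: np.ndarray,
                      n_clusters: int, n_families: int) -> np.ndarray:
    """True where a gene shares its cluster with a same-family gene."""
    in_cluster = cluster_idx >= 0
    table = np.zeros((n_clusters, n_families), dtype=np.int64)
    np.add.at(table, (cluster_idx[in_cluster], labels[in_cluster]), 1)
    mask = np.zeros(len(labels), dtype=bool)
    mask[in_cluster] = table[cluster_idx[in_cluster], labels[in_cluster]] >= 2
    return mask


def cluster_randomization_test(
    genes: Sequence[TrnaGene],
    clusters: ClusterSet | None = None,
    n_rand: int = 1000,
    gap_kb: float = 7.5,
    seed: int | None = 0,
) -> ClusterRandomizationReport:
    """Do same-family genes colocalize in clusters more than chance expects?

    The statistic is the mean over families of the percentage of member
    genes that share a cluster with >= 1 same-family gene; the null
    randomly reassigns genes to families (preserving family sizes) ``n_rand``
    times. A binomial test compares the observed number of colocalizing
    genes with the null-expected colocalization probability.
    """
    if clusters is None:
        clusters = define_clusters(genes, gap_kb)
    gene_ids = [g.gene_id for g in genes]
    fam_ids = sorted({g.family_id for g in genes})
    fam_index = {f: i for i, f in enumerate(fam_ids)}
    labels = np.array([fam_index[g.family_id] for g in genes])
    member = clusters.membership()
    cluster_idx = np.array([member.get(g, -1) for g in gene_ids])

    def mean_family_pct(mask: np.ndarray, lab: np.ndarray) -> float:
        df = pd.DataFrame({"fam": lab, "coloc": mask})
        return float(df.groupby("fam")["coloc"].mean().mean() * 100.0)

    if clusters.n_clusters == 0:
        logger.warning("cluster_randomization_test: no clusters; test skipped")
        return ClusterRandomizationReport(
            0.0, float("nan"), np.array([]), float("nan"), float("nan"),
            0, len(genes), pd.Series(dtype=float), skipped=True)

    obs_mask = _colocalized_mask(cluster_idx, labels, clusters.n_clusters,
                                 len(fam_ids))
    observed_pct = mean_family_pct(obs_mask, labels)
    fam_frac = (pd.DataFrame({"fam": [g.family_id for g in genes],
                              "coloc": obs_mask})
                .groupby("fam")["coloc"].mean() * 100.0)

    rng = np.random.default_rng(seed)
    null_pcts = np.empty(n_rand)
    null_prob_sum = 0.0
    for i in range(n_rand):
        perm = rng.permutation(labels)
        mask = _colocalized_mask(cluster_idx, perm, clusters.n_clusters,
                                 len(fam_ids))
        null_pcts[i] = mean_family_pct(mask, perm)
        null_prob_sum += mask.mean()
    p0 = null_prob_sum / n_rand
    k = int(obs_mask.sum())
    binom_p = float(stats.binomtest(k, len(genes), min(max(p0, 1e-12), 1 - 1e-12),
                                    alternative="two-sided").pvalue)
    empirical_p = float((np.sum(null_pcts >= observed_pct) + 1.0) / (n_rand + 1.0))
    return ClusterRandomizationReport(
        observed_mean_pct=observed_pct,
        null_mean_pct=float(null_pcts.mean()),
        null_pcts=null_pcts, empirical_p=empirical_p, binomial_p=binom_p,
        n_colocalized=k, n_genes=len(genes), family_fractions=fam_frac,
    )


def compensation_vs_clustering(
    results: Sequence[CompensationResult],
    fractions: Mapping[str, float] | pd.Series,
    bins: int = 4,
) -> tuple[float, float]:
    """Chi-square comparison of per-family clustering percentages between
    compensation-significant and non-significant families."""
    fractions = pd.Series(fractions)
    sig = [float(fractions[r.family_id]) for r in results if r.significant]
    non = [float(fractions[r.family_id]) for r in results if not r.significant]
    if len(sig) < 2 or len(non) < 2:
        raise ValueError("need >= 2 families in each group")
    edges = np.linspace(0.0, 100.0, bins + 1)
    edges[-1] += 1e-9
    h_sig, _ = np.histogram(sig, bins=edges)
    h_non, _ = np.histogram(non, bins=edges)
    table = np.vstack([h_sig, h_non])
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table)
    return float(chi2), float(p)
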