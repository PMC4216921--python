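"""Expression calling for tRNA genes, library-size normalization, a
negative-binomial differential-expression test, and PCA on sample-correlation
matrices.

The DE test is a lightweight stand-in for a full shrinkage-based NB
framework: a per-gene Wald test on the log fold change with median-of-ratios
normalization and a moderated dispersion (per-gene method-of-moments
estimate shrunk toward a mean-dispersion trend fitted across genes). An
externally produced DE table can be converted with
:func:`de_results_from_table` so a dedicated tool can be slotted in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix, ExpressionMatrix, SampleKey

logger = logging.getLogger("codonbalance")


# ---------------------------------------------------------------------------
# Expression calling
# ---------------------------------------------------------------------------

def call_expressed_trnas(counts: CountMatrix, min_reads: int = 10) -> set[str]:
    """tRNA genes with >= ``min_reads`` in every replicate of at least one
    (tissue, stage) condition.

    Counts are assumed already windowed to the gene locus plus 100 bp of
    flanking sequence by the upstream read counting.
    """
    conditions = counts.condition_columns()
    for cond, cols in conditions.items():
        if len(cols) < 2:
            raise ValueError(f"condition {cond} has a single replicate; the "
                             "expression rule is defined on both replicates")
    expressed: set[str] = set()
    for cond, cols in conditions.items():
        ok = np.all(counts.counts[:, cols] >= min_reads, axis=1)
        expressed.update(g for g, flag in zip(counts.genes, ok) if flag)
    return expressed


# ---------------------------------------------------------------------------
# Normalization (median-of-ratios)
# ---------------------------------------------------------------------------

def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors; total-count fallback when no gene has
    all-positive counts."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        raise ValueError("all-zero count matrix")
    positive = np.all(counts > 0, axis=1)
    if positive.any():
        logged = np.log(counts[positive])
        ref = logged.mean(axis=1, keepdims=True)  # per-gene geometric mean
        sf = np.exp(np.median(logged - ref, axis=0))
    else:
        warnings.warn("no gene with all-positive counts; falling back to "
                      "total-count size factors", stacklevel=2)
        totals = counts.sum(axis=0)
        if np.any(totals == 0):
            raise ValueError("sample with zero total counts")
        sf = totals / np.exp(np.mean(np.log(totals)))
    return sf


def normalize_counts(counts: CountMatrix) -> ExpressionMatrix:
    """Divide each sample by its median-of-ratios size factor."""
    sf = size_factors(counts.counts)
    logger.info("size factors: %s", np.array2string(sf, precision=3))
    return ExpressionMatrix(list(counts.genes), list(counts.samples),
                            counts.counts / sf, sf)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    gene_id: str
    stage_pair: tuple[str, str, str]  # (stageA, stageB, tissue)
    log2_fold_change: float
    p_value: float
    p_adjusted: float
    significant: bool


def _trended_dispersion(mean: np.ndarray, disp_mom: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu across genes and moderate the per-gene
    method-of-moments estimates toward it.

    Genes whose own estimate exceeds the trend keep a log-space average of
    the two (protecting against underestimated variance); genes below the
    trend use the trend itself.
    """
    ok = (mean > 0) & np.isfinite(disp_mom)
    x = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    y = np.clip(disp_mom[ok], 0.0, None)
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    for _ in range(2):  # re-fit without strong outliers
        fit = np.clip(x @ coef, 1e-8, None)
        keep = y < 10.0 * fit
        if keep.sum() < 10:
            break
        coef, *_ = np.linalg.lstsq(x[keep], y[keep], rcond=None)
    coef = np.clip(coef, 0.0, None)
    trend = np.full_like(mean, 1e-8)
    trend[mean > 0] = np.clip(coef[0] + coef[1] / mean[mean > 0], 1e-8, None)
    out = trend.copy()
    above = ok & (disp_mom > trend)
    out[above] = np.exp(0.5 * (np.log(disp_mom[above]) + np.log(trend[above])))
    return out


def de_test(
    counts: CountMatrix,
    condition_a: tuple[str, str],
    condition_b: tuple[str, str],
    alpha: float = 0.001,
) -> list[DEResult]:
    """Per-gene NB Wald test between two (tissue, stage) conditions.

    Genes with zero counts in both groups are reported with NA p-values and
    excluded from the BH correction.
    """
    conditions = counts.condition_columns()
    for cond in (condition_a, condition_b):
        if cond not in conditions:
            raise KeyError(f"condition {cond} not present in count matrix")
        if len(conditions[cond]) < 2:
            raise ValueError(f"condition {cond} has fewer than 2 replicates")
    cols_a, cols_b = conditions[condition_a], conditions[condition_b]
    sub = counts.counts[:, cols_a + cols_b].astype(float)
    sf = size_factors(sub)
    norm = sub / sf
    na, nb = len(cols_a), len(cols_b)
    ya, yb = norm[:, :na], norm[:, na:]
    ma, mb = ya.mean(axis=1), yb.mean(axis=1)
    va, vb = ya.var(axis=1, ddof=1), yb.var(axis=1, ddof=1)

    # pooled within-group method-of-moments dispersion (per gene)
    m_pool = (na * ma + nb * mb) / (na + nb)
    v_pool = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = np.where(m_pool > 0, (v_pool - m_pool) / m_pool ** 2, np.nan)
    disp = _trended_dispersion(m_pool, disp_mom)

    degenerate = (ma == 0) & (mb == 0)
    c = 0.5  # pseudocount stabilizing the log ratio at low counts
    lfc_ln = np.log(mb + c) - np.log(ma + c)
    # score-type SE: variance of the log condition mean at the pooled mean
    var_ln = (1.0 / (m_pool + c) + disp) * (1.0 / na + 1.0 / nb)
    z = lfc_ln / np.sqrt(var_ln)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[degenerate] = np.nan

    p_adj = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        _, adj, *_ = multipletests(p[tested], method="fdr_bh")
        p_adj[tested] = adj
    pair = (condition_a[1], condition_b[1],
            condition_a[0] if condition_a[0] == condition_b[0]
            else f"{condition_a[0]}/{condition_b[0]}")
    return [
        DEResult(
            gene_id=g, stage_pair=pair,
            log2_fold_change=float(lfc_ln[i] / np.log(2.0)),
            p_value=float(p[i]), p_adjusted=float(p_adj[i]),
            significant=bool(tested[i] and p_adj[i] < alpha),
        )
        for i, g in enumerate(counts.genes)
    ]


def de_results_from_table(df: pd.DataFrame, stage_pair: tuple[str, str, str],
                          alpha: float = 0.001) -> list[DEResult]:
    """Adapt an externally produced DE table (columns gene_id,
    log2_fold_change, p_value, p_adjusted) to the DEResult interface."""
    required = {"gene_id", "log2_fold_change", "p_value", "p_adjusted"}
    if not required.issubset(df.columns):
        raise ValueError(f"external DE table needs columns {sorted(required)}")
    return [
        DEResult(row.gene_id, stage_pair, float(row.log2_fold_change),
                 float(row.p_value), float(row.p_adjusted),
                 bool(row.p_adjusted < alpha))
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# PCA on the sample-correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    samples: list[SampleKey]
    components: np.ndarray          # samples x components score matrix
    variance_fraction: np.ndarray
    variance_fraction_of_remaining: np.ndarray

    def scores(self, component: int) -> pd.Series:
        return pd.Series(self.components[:, component],
                         index=[s.label for s in self.samples])


def spearman_pca(expr: ExpressionMatrix,
                 gene_subset: list[str] | None = None) -> PcaResult:
    """PCA of the samples x samples Spearman correlation matrix.

    The correlation matrix is column-centered and decomposed by SVD; scores,
    raw variance fractions, and each component's fraction of the variance
    remaining after the preceding components are reported.
    """
    values = expr.values
    if gene_subset is not None:
        idx = {g: i for i, g in enumerate(expr.genes)}
        values = values[[idx[g] for g in gene_subset]]
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA")
    const = np.ptp(values, axis=0) == 0
    if const.any():
        bad = [expr.samples[j].label for j in np.nonzero(const)[0]]
        raise ValueError(f"constant expression vector for sample(s) {bad}; "
                         "Spearman correlation undefined")
    corr, _ = stats.spearmanr(values, axis=0)
    corr = np.atleast_2d(corr)
    centered = corr - corr.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    scores = u * s
    # deterministic sign: largest-magnitude score positive
    for k in range(scores.shape[1]):
        j = np.argmax(np.abs(scores[:, k]))
        if scores[j, k] < 0:
            scores[:, k] *= -1
    var = s ** 2
    frac = var / var.sum()
    remaining = var.sum() - np.concatenate([[0.0], np.cumsum(var)[:-1]])
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_rem = np.where(remaining > 0, var / remaining, 0.0)
    return PcaResult(list(expr.samples), scores, frac, frac_rem)
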