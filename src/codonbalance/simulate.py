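"""Synthetic genomes, tRNA annotations, and count matrices with the
statistical structure the downstream analysis assumes.

The generator emulates a two-tissue, six-stage, two-replicate developmental
design with negative-binomially distributed counts:

* protein-coding log-means = gene baseline + a dominant tissue effect + a
  monotone-ish stage trend + replicate noise;
* tRNA genes grouped into anticodon isoacceptor families and placed on
  chromosomes so that a configurable fraction lies in chains with inter-gene
  gaps below ``cluster_gap_kb``;
* isoacceptor family abundance coupled to the expression-weighted codon
  demand at a configurable target Spearman correlation (``coupling_rho``),
  via a Gaussian-copula construction on the demand ranks;
* designated "compensated" families carry two anti-correlated expression
  clusters whose per-stage family total is held constant.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import (
    CountMatrix,
    SampleKey,
    TranscriptRecord,
    TrnaGene,
    load_genetic_code,
    make_family_id,
    reverse_complement,
)
from .usage import SENSE_CODONS, codon_count_matrix, weighted_usage

logger = logging.getLogger("codonbalance")

DEFAULT_STAGES = ("E15.5", "E18.5", "P0.5", "P4", "P22", "P29")
DEFAULT_TISSUES = ("liver", "brain")

TRNA_GENE_LENGTH = 72  # nt, typical tRNA gene


def all_watson_crick_families() -> list[str]:
    """All 61 possible isoacceptor families (one per sense codon)."""
    code = load_genetic_code()
    fams = [make_family_id(code.amino_acid(c), reverse_complement(c))
            for c in sorted(code.sense_codons)]
    return sorted(fams)


def default_encoded_families() -> list[str]:
    """The default genomically encoded family set (46 families, 15 orphans).

    Follows the standard eukaryotic wobble economy: in each four-codon box
    decoded by a single isotype the G34 anticodon is absent (its C-ending
    codon is read by the inosine-forming A34 isoacceptor), and in each split
    NNY two-codon box the A34 anticodon is absent (the T-ending codon is read
    by the G34 isoacceptor). The three-codon Ile box keeps its A34 anticodon.
    """
    code = load_genetic_code()
    dropped: set[str] = set()
    for b1 in "ACGT":
        for b2 in "ACGT":
            box = [b1 + b2 + b3 for b3 in "ACGT"]
            aas = {c: code.table[c] for c in box}
            if all(aa != "*" for aa in aas.values()) and len(set(aas.values())) == 1:
                dropped.add(reverse_complement(b1 + b2 + "C"))  # G34 absent
            else:
                c_t, c_c, c_a = b1 + b2 + "T", b1 + b2 + "C", b1 + b2 + "A"
                if (aas[c_t] != "*" and aas[c_t] == aas[c_c] and aas[c_a] != aas[c_t]):
                    dropped.add(reverse_complement(c_t))  # A34 absent
    out = []
    for c in sorted(code.sense_codons):
        anticodon = reverse_complement(c)
        if anticodon not in dropped:
            out.append(make_family_id(code.amino_acid(c), anticodon))
    return sorted(out)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset (defaults mirror the study design
    at desk scale: two tissues x six stages x two replicates)."""

    n_pc_genes: int = 2000
    n_trna_genes: int = 300
    n_families: int = 46
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates: int = 2
    nb_dispersion: float = 0.05
    # log-scale effect sizes; tissue >> stage so sample-correlation PCA
    # separates tissues on PC1 and orders stages on PC2
    tissue_effect_sd: float = 1.2
    stage_effect_sd: float = 0.3
    #: fraction of the stage-trend variance shared between tissues
    #: (developmental programs are partly tissue-independent)
    stage_shared_fraction: float = 0.7
    noise_sd: float = 0.1
    gene_baseline_sd: float = 1.0
    pc_base_mean: float = 200.0
    # codon-anticodon interface
    coupling_rho: float = 0.7
    family_abundance_sd: float = 1.0
    # compensation structure
    compensated_families: tuple[str, ...] = ()
    compensation_amplitude: float = 0.3
    # tRNA genome layout
    cluster_gap_kb: float = 7.5
    clustered_fraction: float = 0.9
    cluster_family_bias: float = 0.8
    family_size_concentration: float = 1.5
    n_chromosomes: int = 19
    chrom_length_mb: float = 150.0
    # tRNA expression
    trna_mean_reads: float = 500.0
    trna_inactive_fraction: float = 0.28
    trna_share_stage_sd: float = 0.25
    # CDS model
    codon_model: str = "skewed"  # "skewed" (Dirichlet) or "uniform"
    codon_concentration: float = 5.0
    mean_cds_codons: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families > 47:
            raise ValueError("n_families must be <= 47 (non-Sec anticodon families)")
        if self.n_families < 1 or self.n_trna_genes < self.n_families:
            raise ValueError("need at least one tRNA gene per family")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0.0 <= self.coupling_rho <= 1.0:
            raise ValueError("coupling_rho must be in [0, 1]")
        if self.codon_model not in {"skewed", "uniform"}:
            raise ValueError("codon_model must be 'skewed' or 'uniform'")

    @property
    def sample_keys(self) -> list[SampleKey]:
        return [SampleKey(t, s, r)
                for t in self.tissues for s in self.stages
                for r in range(1, self.replicates + 1)]


@dataclass
class SyntheticGenome:
    """Output of :func:`generate_genome`."""

    transcripts: list[TranscriptRecord]
    trna_genes: list[TrnaGene]
    pc_coords: pd.DataFrame  # gene_id, chrom, start, end
    families: list[str]
    codon_weights: pd.Series  # sampling weights over sense codons
    config: SimConfig

    def __iter__(self):  # allow (transcripts, trna_genes) unpacking
        return iter((self.transcripts, self.trna_genes))


@dataclass
class SimTruth:
    """Ground truth recorded for every generated dataset."""

    mrna_mean: pd.DataFrame  # genes x samples true NB means
    trna_mean: pd.DataFrame
    family_of: dict[str, str]
    compensated_clusters: dict[str, tuple[tuple[str, ...], tuple[str, ...]]]
    demand_by_tissue: dict[str, pd.Series]  # relative codon demand
    family_abundance_by_tissue: dict[str, pd.Series]
    true_de: dict[tuple[str, str, str], set[str]]  # (tissue, stageA, stageB)
    coupling_rho: float
    inactive_trnas: set[str]


def nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws parameterized by mean mu and dispersion a: var = mu + a*mu^2."""
    mean = np.asarray(mean, dtype=float)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _family_sizes(rng: np.random.Generator, n_genes: int, n_families: int,
                  concentration: float) -> np.ndarray:
    """Skewed family sizes by largest-remainder allocation, each >= 1."""
    w = rng.gamma(concentration, size=n_families)
    w /= w.sum()
    raw = w * n_genes
    sizes = np.floor(raw).astype(int)
    remainder = n_genes - sizes.sum()
    order = np.argsort(-(raw - sizes))
    sizes[order[:remainder]] += 1
    while np.any(sizes < 1):
        sizes[np.argmin(sizes)] += 1
        sizes[np.argmax(sizes)] -= 1
    return sizes


def generate_genome(config: SimConfig) -> SyntheticGenome:
    """Synthesize CDS sequences, tRNA gene annotation, and pc-gene coordinates."""
    rng = np.random.default_rng([config.seed, 1])
    code = load_genetic_code()

    # --- codon sampling weights -------------------------------------------
    if config.codon_model == "uniform":
        weights = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    else:
        weights = rng.dirichlet(np.full(len(SENSE_CODONS), config.codon_concentration))
    codon_weights = pd.Series(weights, index=SENSE_CODONS)

    # --- CDS sequences -----------------------------------------------------
    codon_arr = np.array(SENSE_CODONS)
    stop_arr = np.array(sorted(code.stop_codons))
    n_codons = np.maximum(
        30, np.rint(np.exp(rng.normal(np.log(config.mean_cds_codons), 0.4,
                                      config.n_pc_genes))).astype(int))
    transcripts = []
    pad = len(str(config.n_pc_genes))
    for i in range(config.n_pc_genes):
        body = rng.choice(len(codon_arr), size=n_codons[i] - 2, p=weights)
        cds = "ATG" + "".join(codon_arr[body]) + str(rng.choice(stop_arr))
        transcripts.append(TranscriptRecord(f"pc{i:0{pad}d}", cds))

    # --- protein-coding gene coordinates ----------------------------------
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_len = int(config.chrom_length_mb * 1e6)
    pc_chrom = rng.choice(chroms, size=config.n_pc_genes)
    pc_start = rng.integers(0, chrom_len, size=config.n_pc_genes)
    pc_len = 3 * n_codons * 2  # gene span ~ 2x CDS
    pc_coords = pd.DataFrame({
        "gene_id": [t.gene_id for t in transcripts],
        "chrom": pc_chrom, "start": pc_start, "end": pc_start + pc_len,
    })

    # --- tRNA families -----------------------------------------------------
    catalogue = default_encoded_families()
    if config.n_families > len(catalogue):
        extra = [f for f in all_watson_crick_families() if f not in catalogue]
        catalogue = catalogue + extra
    families = sorted(catalogue[: config.n_families])
    sizes = _family_sizes(rng, config.n_trna_genes, len(families),
                          config.family_size_concentration)

    # --- layout units: clusters (2-5 genes) and isolated genes --------------
    # With cluster_family_bias, a cluster is drawn from a single family
    # (family chosen first, size capped by its remaining quota), mirroring the
    # observation that same-family tRNA genes tend to colocalize.
    quota = dict(zip(families, (int(s) for s in sizes)))
    unit_labels: list[list[str]] = []

    def _draw_from_quota(k: int) -> list[str]:
        picks = []
        for _ in range(k):
            fams = [f for f in families if quota[f] > 0]
            if not fams:
                break
            w = np.array([quota[f] for f in fams], dtype=float)
            f = fams[rng.choice(len(fams), p=w / w.sum())]
            quota[f] -= 1
            picks.append(f)
        return picks

    n_remaining = int(round(config.clustered_fraction * config.n_trna_genes))
    while n_remaining >= 2 and sum(quota.values()) >= 2:
        pure_candidates = [f for f in families if quota[f] >= 2]
        if pure_candidates and rng.random() < config.cluster_family_bias:
            w = np.array([quota[f] for f in pure_candidates], dtype=float)
            f = pure_candidates[rng.choice(len(pure_candidates), p=w / w.sum())]
            s = min(int(rng.integers(2, 6)), quota[f], n_remaining)
            if n_remaining - s == 1 and quota[f] > s:
                s += 1  # avoid stranding a single gene when everything clusters
            if quota[f] - s == 1:  # avoid stranding a single family member
                s = s + 1 if n_remaining - s >= 1 else s - 1
            s = max(2, min(s, quota[f], n_remaining))
            quota[f] -= s
            unit_labels.append([f] * s)
        else:
            s = min(int(rng.integers(2, 6)), n_remaining, sum(quota.values()))
            if n_remaining - s == 1 and sum(quota.values()) > s:
                s += 1
            unit_labels.append(_draw_from_quota(s))
        n_remaining -= len(unit_labels[-1])
    unit_labels.extend([lab] for lab in _draw_from_quota(sum(quota.values())))

    # --- place units on chromosomes ----------------------------------------
    gap_nt = config.cluster_gap_kb * 1000.0
    unit_order = rng.permutation(len(unit_labels))
    unit_chrom = rng.choice(chroms, size=len(unit_labels))
    cursor = {c: 0 for c in chroms}
    records: list[tuple[str, int, int, str, str]] = []  # chrom,start,end,strand,family
    for u in unit_order:
        labels = unit_labels[u]
        chrom = unit_chrom[u]
        pos = cursor[chrom] + int(rng.integers(100_000, 1_000_000))
        for j, fam in enumerate(labels):
            if j > 0:
                pos += TRNA_GENE_LENGTH + int(rng.uniform(0.1, 0.85) * gap_nt)
            strand = "+" if rng.random() < 0.5 else "-"
            records.append((chrom, pos, pos + TRNA_GENE_LENGTH, strand, fam))
        cursor[chrom] = pos + TRNA_GENE_LENGTH
    records.sort(key=lambda r: (r[0], r[1]))
    pad_t = len(str(config.n_trna_genes))
    trna_genes = []
    for i, (chrom, start, end, strand, fam) in enumerate(records):
        isotype, _, anticodon = fam.rpartition("-")
        trna_genes.append(TrnaGene(f"trna{i:0{pad_t}d}", chrom, start, end,
                                   strand, anticodon, isotype))

    return SyntheticGenome(transcripts, trna_genes, pc_coords, families,
                           codon_weights, config)


# ---------------------------------------------------------------------------
# Count generation
# ---------------------------------------------------------------------------

def _spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula conversion: the latent Pearson correlation that yields
    a target Spearman correlation (rho_p = 2 sin(pi * rho_s / 6))."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def generate_counts(
    config: SimConfig, genome: SyntheticGenome,
) -> tuple[CountMatrix, CountMatrix, SimTruth]:
    """NB count matrices for mRNA and tRNA plus the recorded ground truth."""
    rng = np.random.default_rng([config.seed, 2])
    samples = config.sample_keys
    stages = list(config.stages)
    tissues = list(config.tissues)
    S, n_samp = len(stages), len(samples)
    x_stage = np.linspace(-1.0, 1.0, S)

    # ----- mRNA true means --------------------------------------------------
    G = config.n_pc_genes
    gene_ids = [t.gene_id for t in genome.transcripts]
    base = rng.normal(np.log(config.pc_base_mean), config.gene_baseline_sd, G)
    tissue_eff = {t: rng.normal(0.0, config.tissue_effect_sd, G) for t in tissues}
    shared = np.sqrt(config.stage_shared_fraction)
    specific = np.sqrt(1.0 - config.stage_shared_fraction)
    slope_shared = rng.normal(0.0, config.stage_effect_sd, G)
    slope = {t: shared * slope_shared
             + specific * rng.normal(0.0, config.stage_effect_sd, G)
             for t in tissues}
    mrna_mean = np.empty((G, n_samp))
    for j, key in enumerate(samples):
        s_idx = stages.index(key.stage)
        log_mu = (base + tissue_eff[key.tissue] + slope[key.tissue] * x_stage[s_idx]
                  + rng.normal(0.0, config.noise_sd, G))
        mrna_mean[:, j] = np.exp(log_mu)
    mrna_counts = nb_sample(rng, mrna_mean, config.nb_dispersion)

    # ----- codon demand per tissue (from true condition means) --------------
    tables = codon_count_matrix(genome.transcripts)
    demand_by_tissue: dict[str, pd.Series] = {}
    for t in tissues:
        cols = [j for j, k in enumerate(samples) if k.tissue == t]
        expr = pd.Series(mrna_mean[:, cols].mean(axis=1), index=gene_ids)
        u = weighted_usage(tables, expr, level="codon").normalize()
        demand_by_tissue[t] = u.as_series()

    # ----- family abundance coupled to demand (Gaussian copula) -------------
    fams = genome.families
    F = len(fams)
    rho_p = _spearman_to_pearson(config.coupling_rho)
    eps = rng.normal(0.0, 1.0, F)  # shared across tissues: stable families
    code = load_genetic_code()
    fam_codon = {f: reverse_complement(f.rpartition("-")[2]) for f in fams}
    family_abundance: dict[str, pd.Series] = {}
    for t in tissues:
        demand = np.array([demand_by_tissue[t].get(fam_codon[f], 0.0) for f in fams])
        ranks = pd.Series(demand).rank(method="average").to_numpy()
        z_dem = norm.ppf((ranks - 0.5) / F)
        latent = rho_p * z_dem + np.sqrt(max(0.0, 1.0 - rho_p ** 2)) * eps
        a = np.exp(config.family_abundance_sd * latent)
        family_abundance[t] = pd.Series(a / a.sum(), index=fams)

    # ----- per-gene tRNA means ----------------------------------------------
    trna_ids = [g.gene_id for g in genome.trna_genes]
    family_of = {g.gene_id: g.family_id for g in genome.trna_genes}
    members: dict[str, list[str]] = {}
    for g in genome.trna_genes:
        members.setdefault(g.family_id, []).append(g.gene_id)

    n_inactive = int(round(config.trna_inactive_fraction * len(trna_ids)))
    inactive = set(rng.choice(trna_ids, size=n_inactive, replace=False)) \
        if n_inactive else set()

    comp_fams = [f for f in config.compensated_families if f in members]
    unknown_comp = set(config.compensated_families) - set(members)
    if unknown_comp:
        raise ValueError(f"compensated_families not in genome: {sorted(unknown_comp)}")
    compensated_clusters: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}

    total_reads = config.trna_mean_reads * len(trna_ids)
    trna_mean = np.zeros((len(trna_ids), n_samp))
    row_of = {gid: i for i, gid in enumerate(trna_ids)}
    amp = config.compensation_amplitude
    for fam, gids in members.items():
        active = [g for g in gids if g not in inactive]
        if fam in comp_fams and len(active) >= 2:
            half = len(active) // 2
            perm = rng.permutation(len(active))
            clu_a = tuple(active[i] for i in perm[:half])
            clu_b = tuple(active[i] for i in perm[half:])
            compensated_clusters[fam] = (clu_a, clu_b)
        for t in tissues:
            fam_total = float(family_abundance[t][fam]) * total_reads
            if fam in compensated_clusters:
                clu_a, clu_b = compensated_clusters[fam]
                w_a = rng.dirichlet(np.ones(len(clu_a)))
                w_b = rng.dirichlet(np.ones(len(clu_b)))
                frac_a = 0.5 + amp * x_stage  # monotone mirror trajectories
                for s_idx in range(S):
                    shares = {}
                    for gid, w in zip(clu_a, w_a):
                        shares[gid] = frac_a[s_idx] * w
                    for gid, w in zip(clu_b, w_b):
                        shares[gid] = (1.0 - frac_a[s_idx]) * w
                    for j, key in enumerate(samples):
                        if key.tissue != t or key.stage != stages[s_idx]:
                            continue
                        for gid, sh in shares.items():
                            trna_mean[row_of[gid], j] = fam_total * sh
            elif active:
                w0 = rng.dirichlet(np.ones(len(active)))
                jitter = np.exp(rng.normal(0.0, config.trna_share_stage_sd,
                                           (len(active), S)))
                shares = w0[:, None] * jitter
                shares /= shares.sum(axis=0, keepdims=True)  # family total exact
                for j, key in enumerate(samples):
                    if key.tissue != t:
                        continue
                    s_idx = stages.index(key.stage)
                    for gi, gid in enumerate(active):
                        trna_mean[row_of[gid], j] = fam_total * shares[gi, s_idx]
        for gid in gids:
            if gid in inactive:
                trna_mean[row_of[gid], :] = 0.5  # background occupancy
    trna_counts = nb_sample(rng, trna_mean, config.nb_dispersion)

    # ----- true DE sets ------------------------------------------------------
    mrna_mean_df = pd.DataFrame(mrna_mean, index=gene_ids,
                                columns=[k.label for k in samples])
    trna_mean_df = pd.DataFrame(trna_mean, index=trna_ids,
                                columns=[k.label for k in samples])
    true_de: dict[tuple[str, str, str], set[str]] = {}
    for t in tissues:
        for a_idx in range(S):
            for b_idx in range(a_idx + 1, S):
                la = (tissue_eff[t] + slope[t] * x_stage[a_idx])
                lb = (tissue_eff[t] + slope[t] * x_stage[b_idx])
                de = {gene_ids[i] for i in
                      np.nonzero(np.abs(lb - la) >= np.log(2.0))[0]}
                true_de[(t, stages[a_idx], stages[b_idx])] = de

    truth = SimTruth(
        mrna_mean=mrna_mean_df, trna_mean=trna_mean_df, family_of=family_of,
        compensated_clusters=compensated_clusters,
        demand_by_tissue=demand_by_tissue,
        family_abundance_by_tissue=family_abundance,
        true_de=true_de, coupling_rho=config.coupling_rho,
        inactive_trnas=inactive,
    )
    mrna_cm = CountMatrix(gene_ids, samples, mrna_counts.astype(np.int64))
    trna_cm = CountMatrix(trna_ids, samples, trna_counts.astype(np.int64))
    return mrna_cm, trna_cm, truth


def simulate_dataset(config: SimConfig):
    """Convenience wrapper: genome + counts in one call."""
    genome = generate_genome(config)
    mrna, trna, truth = generate_counts(config, genome)
    return genome, mrna, trna, truth


# ---------------------------------------------------------------------------
# Focused simulators for calibration studies
# ---------------------------------------------------------------------------

def simulate_de_dataset(
    n_genes: int = 2000,
    n_per_group: int = 2,
    frac_de: float = 0.0,
    lfc: float = 3.0,
    base_mean: float = 100.0,
    base_log_sd: float = 1.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[CountMatrix, set[str]]:
    """Two-condition NB dataset with a known true DE gene set.

    ``frac_de`` of genes get |log2 fold change| = ``lfc`` (random sign) in
    condition B. Returns the count matrix (conditions ("sim","A") and
    ("sim","B")) and the true DE gene ids.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    mu = np.exp(rng.normal(np.log(base_mean), base_log_sd, n_genes))
    n_de = int(round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    sign = rng.choice([-1.0, 1.0], size=n_de)
    log2fc = np.zeros(n_genes)
    log2fc[de_idx] = sign * lfc
    mu_b = mu * 2.0 ** log2fc
    samples = ([SampleKey("sim", "A", r + 1) for r in range(n_per_group)]
               + [SampleKey("sim", "B", r + 1) for r in range(n_per_group)])
    counts = np.column_stack(
        [nb_sample(rng, mu, dispersion) for _ in range(n_per_group)]
        + [nb_sample(rng, mu_b, dispersion) for _ in range(n_per_group)])
    return CountMatrix(genes, samples, counts), {genes[i] for i in de_idx}


def generate_chromatin_marks(
    trna_genes: Sequence[TrnaGene],
    enriched_ids: set[str] | Sequence[str] = (),
    enrich_prob: float = 0.9,
    background_prob: float = 0.2,
    max_offset: int = 400,
    mark_width: int = 200,
    n_random_marks: int = 0,
    chrom_length: int = 150_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Peak intervals placed preferentially near designated tRNA genes.

    Each gene in ``enriched_ids`` receives a nearby mark with probability
    ``enrich_prob`` (others with ``background_prob``), centered within
    ``max_offset`` bp of the gene boundary; ``n_random_marks`` additional
    peaks are scattered per chromosome.
    """
    rng = np.random.default_rng(seed)
    enriched = set(enriched_ids)
    rows = []
    for g in trna_genes:
        p = enrich_prob if g.gene_id in enriched else background_prob
        if rng.random() < p:
            center = int(g.start + rng.integers(-max_offset, max_offset + 1))
            rows.append((g.chrom, max(0, center - mark_width // 2),
                         center + mark_width // 2))
    chroms = sorted({g.chrom for g in trna_genes})
    for chrom in chroms:
        for _ in range(n_random_marks):
            s = int(rng.integers(0, chrom_length))
            rows.append((chrom, s, s + mark_width))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
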