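# codonbalance

Quantitative analysis of the mRNA-codon / tRNA-anticodon interface across
developmental transcriptomes.

During translation, the triplet codons in expressed mRNAs must be matched by
the anticodons of available tRNAs. `codonbalance` implements the statistics
needed to study how this interface behaves when gene expression changes
massively — for example across organ development, where both the
protein-coding transcriptome and Pol III occupancy at tRNA genes (a proxy
for tRNA gene transcription) are remodeled between embryonic and adult
stages. It is aimed at computational biologists with CDS sequences, a tRNA
gene annotation, and mRNA/tRNA count matrices (e.g., RNA-seq and Pol III
ChIP-seq counts) over a tissue x stage x replicate design.

## What it computes

**Expression-weighted usage.** For each library, the usage of codon (or
amino acid) $k$ is

$$U_k = \sum_g n_{g,k}\,\frac{e_g}{L_g/1000},$$

where $n_{g,k}$ counts codon $k$ in gene $g$'s longest CDS, $e_g$ is the
library-size-normalized expression (median-of-ratios size factors), and
$L_g$ the CDS length; relative usage is $u_k = U_k / \sum_j U_j$. On the
tRNA side, isoacceptor family abundance $A_f$ sums normalized Pol III
occupancy over the genes sharing anticodon $f$, and isotype abundance sums
families by amino acid.

**Interface correlation.** Spearman's $\rho$ between $u$ and $A$ over
codons paired with their Watson–Crick anticodon family (codons whose
anticodon is not genomically encoded are excluded). A wobble-corrected
variant assigns each *orphan* codon (no exact Watson–Crick anticodon gene)
to a same-isotype isoacceptor differing only at position 34 under a
configurable wobble rule table (G34→C/T, T34→A/G, A34→T/C/A via inosine,
C34→G), then splits each family's abundance over the codons it serves
proportionally to codon demand.

**Null models.** 100 artificial transcriptomes per condition, built by
permuting expression values across genes (expressed-only or padded to all
annotated genes), give background distributions for every profile and for
the interface correlation.

**Family dynamics.** A within-family compensation test: all pairwise
Spearman correlations of member-gene expression across ordered stages,
compared by a χ² goodness-of-fit against a null enumerated from permuted
stage orders (720 orderings at 6 stages); Bonferroni correction over
families with ≥ 6 genes. Genomic clusters chain tRNA genes within 7.5 kb;
a 1000-fold family-label randomization asks whether same-family genes
colocalize more than chance.

**Genome context.** Kolmogorov–Smirnov comparison of the ratio of
up-regulated to total protein-coding neighbors around up-regulated vs
stable tRNA genes (10/50/100 kb windows), and Fisher's exact association of
chromatin-mark peaks within 0.1/0.5/1 kb of tRNA gene sets.

**Supporting machinery.** tRNA expression calling (≥ 10 reads in both
replicates of at least one condition), a vectorized negative-binomial Wald
DE test with trended moment dispersion (an external DE table can be slotted
in), PCA of the sample-wise Spearman correlation matrix, and a
synthetic-data generator that emulates the full study design — two tissues,
six stages, two replicates, NB counts, genomically clustered tRNA families,
a tunable codon–anticodon coupling, and designated compensated families —
so the entire pipeline runs and is testable with no external data.

## Worked example

```python
import codonbalance as cb

cfg = cb.SimConfig(n_pc_genes=800, n_trna_genes=250, coupling_rho=0.7, seed=3)
genome = cb.generate_genome(cfg)
mrna, trna, truth = cb.generate_counts(cfg, genome)

expressed = cb.call_expressed_trnas(trna)            # >=10 reads, both reps
mn = cb.normalize_counts(mrna)
tn = cb.normalize_counts(trna.subset_genes(sorted(expressed)))

tables = cb.codon_count_matrix(genome.transcripts)
codon_u = cb.weighted_usage(tables, mn.sample_values("liver", "P4")).normalize()
anti_u = cb.anticodon_abundance(tn.sample_values("liver", "P4"), genome.trna_genes)

rho, p, n = cb.interface_correlation(codon_u, anti_u)
rho_w, p_w, n_w = cb.wobble_corrected_correlation(codon_u, anti_u)
print(f"expressed tRNAs: {len(expressed)}/{len(trna.genes)}")
print(f"interface rho = {rho:.3f} (p = {p:.2g}, n = {n} codon pairs)")
print(f"wobble-corrected rho = {rho_w:.3f} over {n_w} codons")
```

Output:

```
expressed tRNAs: 180/250
interface rho = 0.688 (p = 3.3e-07, n = 43 codon pairs)
wobble-corrected rho = 0.585 over 57 codons
```

The 180/250 expressed genes reflect the generator's inactive fraction; the
observed ρ ≈ 0.69 recovers the designed coupling of 0.7 between codon
demand and anticodon supply, and the wobble correction — which reassigns
orphan codons to their inosine/G34 decoders and splits wobbling families'
abundance by demand — shifts the correlation moderately downward while it
stays strong, now over 57 decodable codons.

The same analysis runs from the shell via the `codonbalance` CLI
(`simulate`, `usage`, `background`, `wobble`, `de`, `pca`, `compensation`,
`clusters`, `coloc`, `chromatin`, `run`) driven by a YAML config; outputs
are TSVs plus a `manifest.json` recording the config hash and seeds.

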