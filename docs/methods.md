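# Methods

## Model and procedure

The package treats the codon–anticodon interface as two relative frequency
vectors. The mRNA side is the expression-weighted codon usage
$U_k = \sum_g n_{g,k}\, e_g / (L_g/1000)$, normalized to
$u_k = U_k/\sum_j U_j$; the weight is expression per kilobase of the
*counted* sequence, which we take to be the longest CDS because that is
where the codons are counted (a `lengths` argument accepts full-transcript
lengths instead). Stop codons are retained in raw count tables for QC but
excluded from profiles, as is selenocysteine throughout. The tRNA side sums
library-size-normalized Pol III occupancy over the genes of each anticodon
isoacceptor family and normalizes; isotype profiles aggregate families by
amino acid. The interface statistic is Spearman's ρ between $u$ and the
abundance of each codon's Watson–Crick anticodon family (the reverse
complement), over codons whose family is genomically encoded.

Normalization uses median-of-ratios size factors computed over genes with
all-positive counts, with a logged total-count fallback when no such gene
exists. tRNA expression calling requires ≥ 10 reads in every replicate of at
least one tissue–stage condition; counts are assumed already windowed to the
locus ± 100 bp by the upstream read counting — that windowing is a counting
concern, not re-implemented here.

### Wobble correction

Orphan codons are sense codons whose exact Watson–Crick anticodon is absent
from the encoded family set. Each orphan is assigned to an encoded family of
the same isotype whose anticodon differs only at position 34 and whose
wobble base can read the orphan's third base under a configurable rule
table; defaults are the classic rules plus inosine (G34→{C,T}, T34→{A,G},
A34→{T,C,A}, C34→{G}). Because the isotype constraint almost always leaves a
single candidate, the deterministic preference order G34 > A34 > T34 > C34
matters only for user-extended rule tables. A family serving several codons
has its abundance divided among them proportionally to codon demand (equal
split if all demands are zero), so total availability conserves total mapped
abundance exactly; unmatchable orphans are logged and excluded from the
corrected correlation rather than imputed.

### Null models

Artificial transcriptomes permute the observed expression values across
genes. In `expressed` mode the permutation is measure-preserving on the
observed multiset; in `all_annotated` mode the multiset is padded with zeros
up to the annotated universe before permuting, which preserves the observed
totals (resampling with replacement would not). One hundred shuffles per
condition give mean background profiles and a set of background interface
correlations; shuffled mRNA replicate *i* is paired with shuffled tRNA
replicate *i* by default, with a crossed all-pairs mode behind a flag. The
observed ρ is summarized against the background by the empirical exceedance
$(\#\{\rho_{bg} \ge \rho_{obs}\}+1)/(n+1)$.

### Compensation test

For a family's genes × stages matrix (replicate means, stage-ordered), the
observed statistic is the set of all pairwise Spearman correlations across
stages. Since a rank correlation depends only on the relative ordering of
the two stage vectors, the null enumerates the $S!$ permutations of one
member of each pair ($720$ at six stages; beyond the cap a seeded sample of
720 orderings is drawn). Both distributions are binned on 20 equal-width
bins over $[-1,1]$; bins are then accumulated left-to-right until each
group's null-expected count reaches 5 (trailing remainder merged into the
last group). This order-preserving merge keeps the two tails separate from
the center, which is what distinguishes a bimodal correlation distribution
from the unimodal null — a symmetric smallest-bin merge was found to
collapse small families into an uninformative two-bin split. The χ²
goodness-of-fit p-value is Bonferroni-corrected (BH optional) across
families with ≥ 6 genes; families with 3–5 genes are tested but excluded
from the corrected report, smaller ones skipped. When significant, the two
expression clusters are read off the sign of the leading eigenvector of the
gene–gene correlation matrix. A descriptive bimodality score is emitted but
is not the decision rule. Note the χ² treats the pairwise correlations as
independent; for i.i.d. noise sample correlations of distinct pairs are
asymptotically uncorrelated, and the measured type-I error at α = 0.05 is
below nominal (see the acceptance tests).

### Clusters and genome context

Genomic clusters chain genes per chromosome whose end-to-start gaps are
≤ 7.5 kb (maximal chains of ≥ 2 genes; strand ignored; intergenic distance
rather than midpoints, since fixed-length tRNA genes make the two readings
equivalent in practice). The family-colocalization statistic is the mean
over families of the percentage of members sharing a cluster with a
same-family gene; its null redistributes family labels over genes 1000
times. Both a binomial test (observed colocalizing genes vs the
null-expected probability) and the empirical permutation p-value are
reported. The binomial test assumes independence across genes, which
clustering violates; it is measurably anti-conservative on null layouts,
so calibration checks use the permutation p-value.

Colocalization expands each tRNA gene's interval symmetrically by the
window, computes $r_t = u_t/a_t$ (up-regulated over total protein-coding
neighbors, the up-regulated genes included in the total), drops tRNA genes
with no neighbor, and compares up-regulated vs non-DE tRNA genes by a
two-sample KS test per window and DE threshold. Chromatin association marks
a gene as mark-positive when any peak intersects
$[\mathrm{start}-d, \mathrm{end}+d]$ and applies a two-sided Fisher exact
test to the 2×2 set-membership × mark-presence table.

### DE stand-in and PCA

The differential-expression test is a vectorized NB Wald test: median-of-
ratios normalization on the two conditions, per-gene method-of-moments
dispersion from pooled within-group variances, a parametric trend
$\alpha(\mu)=a_0+a_1/\mu$ fitted across genes (two outlier-trimmed
refits), and moderation that uses the trend unless the per-gene estimate
exceeds it, in which case the log-space mean of the two is used. The Wald
statistic uses the log ratio of pseudocounted group means with a score-type
variance evaluated at the pooled mean, and BH correction across testable
genes (all-zero genes reported NA). This is deliberately a calibrated
stand-in, not a reimplementation of a full shrinkage framework; an adapter
accepts externally produced DE tables, and an independent cross-check
against pydeseq2's gene ranking is part of the test suite.

PCA is applied to the samples × samples Spearman correlation matrix
(column-centered, SVD), as stabilized rank-based structure is what the
tissue/stage design shows most cleanly. Both raw variance fractions and
each component's fraction of the *remaining* variance are reported, because
the stage axis is best expressed as a share of what tissue identity leaves
over. Signs are fixed deterministically (largest-magnitude score positive).

## Synthetic-data generator

The generator is first-class, tested code and defines the study conditions:
two tissues × six ordered stages (E15.5 … P29) × two replicates, NB counts
with dispersion 0.05. Protein-coding log-means are gene baseline
(SD 1.0) + tissue effect (SD 1.2) + a linear stage trend (SD 0.3, 70% of its
variance shared between tissues — developmental programs are partly
tissue-independent, and without a shared component no single principal
component can order stages in both tissues) + replicate noise (SD 0.1).
These scales give a realistic ~1.6 ln-unit cross-gene spread; heavier tails
leave too few effective genes for the shuffle-background estimator to
converge.

CDS sequences are drawn codon-by-codon (ATG start, one stop) from a
Dirichlet-skewed codon frequency model (concentration 5 over the 61 sense
codons, ~40–50% relative spread, matching real mammalian codon usage). A
uniform model is available but not the default: with near-equal codon
frequencies the demand ranks are dominated by sampling noise and a target
codon–anticodon coupling is ill-posed.

tRNA genes are allocated to anticodon families with gamma-skewed sizes. The
default encoded set holds 46 of the 61 Watson–Crick families, derived from
standard eukaryotic wobble economy (G34 absent in single-isotype four-codon
boxes, A34 absent in split NNY boxes, inosine retained for Ile), which
yields exactly 15 orphan codons. Genes are laid out in chains of 2–5 with
intra-chain gaps below 7.5 kb (a configurable clustered fraction, default
0.9) separated by 100 kb–1 Mb; a cluster is drawn from a single family with
probability `cluster_family_bias` (default 0.8, reflecting observed
same-family clustering; set 0 for spatial-null layouts).

Family abundance is coupled to realized codon demand at the *family* level
— families, not individual genes, are the stable unit — via a Gaussian
copula: normal scores of the demand ranks are mixed with family-specific
noise at latent correlation $2\sin(\pi\rho_s/6)$, so the realized Spearman
correlation targets `coupling_rho` (default 0.7). The noise is drawn once
and shared across tissues and stages, making anticodon pools stable across
development. Within a family, member-gene shares are Dirichlet with
per-stage jitter renormalized so the family total is exact; 28% of genes
are inactive (background occupancy ~0.5 reads), mirroring the expressed
fraction of an annotated tRNA gene set. Designated compensated families are
split into two clusters whose shares follow mirrored monotone trajectories
(amplitude 0.3) with the per-stage family total held constant, so
within-cluster mean-space correlations are +1 and cross-cluster −1 before
count noise.

What the generator does **not** emulate: read-level artifacts (mapping,
multi-mapping reallocation, GC bias), per-gene dispersion variation,
correlated gene programs beyond the single shared stage axis,
sequence-level realism of CDSs or tRNA loci, and chromatin structure beyond
optionally placing peaks near designated genes. Passing tests therefore
demonstrate that the statistics behave correctly under the assumed
generative structure, not that real libraries satisfy that structure.

## Numerical choices and edge cases

* All "sums to 1" checks at 1e-9; conservation of redistributed abundance
  is exact to floating-point and asserted at 1e-9.
* Stage order always comes from configuration; lexical sorting is never
  used (E15.5 < P0.5 sorts wrongly as text).
* Quantile splits for high/low expression (defaults 10%) break ties by
  gene_id for determinism.
* Genes with ambiguous bases or non-multiple-of-3 CDS are dropped with
  logged counts, never imputed; constant trajectories are dropped from the
  compensation test with a warning.
* Every stochastic step takes an explicit seed; identical configs produce
  byte-identical pipeline outputs.
* Interface correlations need ≥ 4 codon pairs; compensation needs ≥ 3
  usable genes and ≥ 4 stages; conditions need ≥ 2 replicates everywhere.

## Known limitations

* The compensation χ² inherits the pairwise-correlation independence
  approximation; its measured type-I error is conservative at the tested
  design but is not guaranteed for very small stage counts.
* The binomial family-colocalization test is anti-conservative under
  clustered layouts (use the reported permutation p-value for inference).
* The DE stand-in targets calibration at small replicate counts, not exact
  agreement with any specific shrinkage implementation; fold-change
  shrinkage is out of scope.
* The wobble rule table is biochemical shorthand; modified-base effects
  beyond inosine are not modeled, and the orphan assignment may differ from
  curated decoding tables for isotypes with several candidates.
* Amino-acid–level interface correlations pair keys by identity, which
  assumes isotype labels use the same amino-acid code as the genetic-code
  table (the generator uses one-letter codes).
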