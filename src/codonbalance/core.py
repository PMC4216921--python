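"""Domain types, the genetic code, and readers/writers for on-disk formats.

Conventions used throughout the package:

* DNA alphabet everywhere; anticodons are stored as DNA (T, not U) written
  5'->3', i.e. the Watson-Crick anticodon of a codon is its reverse
  complement.
* Genomic coordinates are 0-based half-open (BED dialect) both in memory and
  on disk.
* Developmental stage order always comes from an explicit ordered list (a
  config value), never from lexical sorting: "E15.5" < "P0.5" sorts wrongly
  as text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("codonbalance")

STOP = "*"
DNA_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: chromosome names treated as mitochondrial (mitochondrial tRNAs are
#: excluded from all analyses)
MITO_CHROMS = frozenset({"chrM", "chrMT", "MT", "M"})

#: isotype spellings for selenocysteine tRNAs (flagged and excluded from
#: downstream statistics)
SELENOCYSTEINE_ISOTYPES = frozenset({"SeC", "Sec", "SEC"})


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticCode:
    """The standard nuclear genetic code: 64 codons, 61 sense, 3 stop, 20 aa."""

    table: Mapping[str, str]
    sense_codons: frozenset[str]
    stop_codons: frozenset[str]
    amino_acids: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"expected 64 codons, got {len(self.table)}")
        if len(self.stop_codons) != 3 or len(self.sense_codons) != 61:
            raise ValueError("sense/stop partition must be 61/3")
        if len(self.amino_acids) != 20:
            raise ValueError(f"expected 20 amino acids, got {len(self.amino_acids)}")
        if self.sense_codons | self.stop_codons != set(self.table):
            raise ValueError("sense and stop codons must partition the table")

    def amino_acid(self, codon: str) -> str:
        """One-letter amino-acid code, or '*' for a stop codon."""
        return self.table[codon]

    def codons_for(self, amino_acid: str) -> list[str]:
        return sorted(c for c, aa in self.table.items() if aa == amino_acid)

    def anticodon(self, codon: str) -> str:
        """The Watson-Crick anticodon (reverse complement), 5'->3'."""
        return reverse_complement(codon)


@lru_cache(maxsize=1)
def load_genetic_code() -> GeneticCode:
    """The standard nuclear genetic code from the NCBI table (id 1)."""
    ncbi = CodonTable.unambiguous_dna_by_id[1]
    table: dict[str, str] = dict(ncbi.forward_table)
    for codon in ncbi.stop_codons:
        table[codon] = STOP
    return GeneticCode(
        table=table,
        sense_codons=frozenset(c for c, aa in table.items() if aa != STOP),
        stop_codons=frozenset(ncbi.stop_codons),
        amino_acids=frozenset(aa for aa in table.values() if aa != STOP),
    )


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptRecord:
    """A protein-coding gene's representative (longest) CDS."""

    gene_id: str
    cds: str

    def __post_init__(self) -> None:
        if len(self.cds) % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {len(self.cds)} not divisible by 3"
            )
        if set(self.cds) - set(DNA_BASES):
            raise ValueError(f"{self.gene_id}: CDS contains non-ACGT characters")

    @property
    def length_nt(self) -> int:
        return len(self.cds)

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3


def make_family_id(isotype: str, anticodon: str) -> str:
    return f"{isotype}-{anticodon}"


@dataclass(frozen=True)
class TrnaGene:
    """A tRNA gene locus with anticodon, isotype and isoacceptor family."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    anticodon: str
    isotype: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.gene_id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if len(self.anticodon) != 3 or set(self.anticodon) - set(DNA_BASES):
            raise ValueError(f"{self.gene_id}: anticodon {self.anticodon!r} is not a DNA triplet")

    @property
    def family_id(self) -> str:
        return make_family_id(self.isotype, self.anticodon)

    @property
    def is_selenocysteine(self) -> bool:
        return self.isotype in SELENOCYSTEINE_ISOTYPES


class SampleKey(NamedTuple):
    """One library: a tissue at a developmental stage, one replicate."""

    tissue: str
    stage: str
    replicate: int

    @property
    def label(self) -> str:
        return f"{self.tissue}.{self.stage}.rep{self.replicate}"

    @classmethod
    def from_label(cls, label: str) -> "SampleKey":
        parts = label.split(".")
        if len(parts) < 3 or not parts[-1].startswith("rep"):
            raise ValueError(f"cannot parse sample label {label!r} (want tissue.stage.repN)")
        try:
            replicate = int(parts[-1][3:])
        except ValueError as exc:
            raise ValueError(f"bad replicate in sample label {label!r}") from exc
        if replicate < 1:
            raise ValueError(f"replicate must be >= 1 in {label!r}")
        return cls(tissue=parts[0], stage=".".join(parts[1:-1]), replicate=replicate)


# ---------------------------------------------------------------------------
# Matrices and profiles
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw genes x samples counts with (tissue, stage, replicate) metadata."""

    genes: list[str]
    samples: list[SampleKey]
    counts: np.ndarray  # shape (n_genes, n_samples), non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape does not match genes x samples")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene_ids")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate samples")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.genes, name="gene_id"),
            columns=[s.label for s in self.samples],
        )

    def condition_columns(self) -> dict[tuple[str, str], list[int]]:
        """Column indices per (tissue, stage) condition, replicate-ordered."""
        out: dict[tuple[str, str], list[int]] = {}
        for j, s in enumerate(self.samples):
            out.setdefault((s.tissue, s.stage), []).append(j)
        return out

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        idx = {g: i for i, g in enumerate(self.genes)}
        rows = [idx[g] for g in gene_ids]
        return CountMatrix(list(gene_ids), list(self.samples), self.counts[rows])


@dataclass
class ExpressionMatrix:
    """Library-size-normalized genes x samples values plus the size factors."""

    genes: list[str]
    samples: list[SampleKey]
    values: np.ndarray  # float
    size_factors: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.genes, name="gene_id"),
            columns=[s.label for s in self.samples],
        )

    def sample_values(self, tissue: str, stage: str, replicate_mean: bool = True) -> pd.Series:
        """Per-gene expression for one condition (mean over replicates)."""
        cols = [j for j, s in enumerate(self.samples)
                if s.tissue == tissue and s.stage == stage]
        if not cols:
            raise KeyError(f"no samples for ({tissue}, {stage})")
        v = self.values[:, cols]
        if replicate_mean:
            v = v.mean(axis=1)
        else:
            v = v[:, 0]
        return pd.Series(v, index=self.genes)


PROFILE_KINDS = ("codon", "amino_acid", "anticodon", "isotype")


@dataclass
class UsageProfile:
    """Per-key non-negative usage vector; when normalized it sums to 1.

    ``kind`` says what the keys are: codons, one-letter amino acids,
    anticodon isoacceptor family ids, or amino-acid isotypes.
    """

    keys: list[str]
    values: np.ndarray
    kind: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"kind must be one of {PROFILE_KINDS}")
        if len(self.keys) != len(self.values):
            raise ValueError("keys/values length mismatch")
        if np.any(self.values < 0):
            raise ValueError("usage values must be non-negative")
        if self.normalized and abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("normalized profile does not sum to 1 within 1e-9")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.keys, name=self.kind)

    def __getitem__(self, key: str) -> float:
        return float(self.values[self.keys.index(key)])

    def normalize(self) -> "UsageProfile":
        total = float(self.values.sum())
        if total <= 0:
            raise ValueError(f"cannot normalize all-zero {self.kind} profile")
        return UsageProfile(list(self.keys), self.values / total, self.kind, normalized=True)


# ---------------------------------------------------------------------------
# FASTA (CDS)
# ---------------------------------------------------------------------------

def read_cds_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read CDS sequences; keep the longest record per gene_id.

    Sequences are upper-cased. Records whose length is not divisible by 3 or
    that contain ambiguity codes are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    longest: dict[str, str] = {}
    order: list[str] = []
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        seq = str(rec.seq).upper()
        if rec.id not in longest:
            order.append(rec.id)
            longest[rec.id] = seq
        elif len(seq) > len(longest[rec.id]):
            longest[rec.id] = seq
    if n_records == 0:
        raise ValueError(f"empty FASTA: {path}")
    out: list[TranscriptRecord] = []
    n_dropped = 0
    for gene_id in order:
        seq = longest[gene_id]
        if len(seq) % 3 != 0 or set(seq) - set(DNA_BASES):
            n_dropped += 1
            continue
        out.append(TranscriptRecord(gene_id, seq))
    if n_dropped:
        logger.warning("read_cds_fasta: dropped %d/%d genes (length %% 3 != 0 or "
                       "ambiguity codes)", n_dropped, len(longest))
    return out


def write_cds_fasta(path: str | Path, transcripts: Iterable[TranscriptRecord]) -> None:
    records = [SeqRecord(Seq(t.cds), id=t.gene_id, description="") for t in transcripts]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# tRNA annotation (BED-like, 7 columns)
# ---------------------------------------------------------------------------

TRNA_BED_COLUMNS = ("chrom", "start", "end", "gene_id", "isotype", "anticodon", "strand")


def read_trna_annotation(path: str | Path) -> list[TrnaGene]:
    """Read a 7-column tab-separated tRNA annotation.

    Columns: chrom, start, end, gene_id, isotype, anticodon, strand with
    0-based half-open coordinates. Mitochondrial rows are dropped.
    Selenocysteine genes are returned (flagged via ``is_selenocysteine``) so
    callers can exclude them from statistics.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genes: list[TrnaGene] = []
    n_mito = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 tab-separated fields, "
                                 f"got {len(fields)}")
            chrom, start, end, gene_id, isotype, anticodon, strand = fields
            if len(anticodon) != 3:
                raise ValueError(f"{path}:{lineno}: anticodon {anticodon!r} is not length 3")
            if chrom in MITO_CHROMS:
                n_mito += 1
                continue
            try:
                gene = TrnaGene(gene_id, chrom, int(start), int(end), strand,
                                anticodon.upper(), isotype)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            genes.append(gene)
    if n_mito:
        logger.info("read_trna_annotation: dropped %d mitochondrial rows", n_mito)
    return genes


def write_trna_annotation(path: str | Path, genes: Iterable[TrnaGene]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write("\t".join([g.chrom, str(g.start), str(g.end), g.gene_id,
                                g.isotype, g.anticodon, g.strand]) + "\n")


# ---------------------------------------------------------------------------
# Count matrices (TSV)
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, stage_order: Sequence[str] | None = None) -> CountMatrix:
    """Read a TSV count matrix: first column gene_id, then one column per
    sample labelled ``tissue.stage.repN``.

    ``stage_order``, when given, validates stage labels and orders samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene_ids")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample columns")
    samples = [SampleKey.from_label(c) for c in df.columns]
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        as_float = values.astype(float)
        if np.any(as_float != np.floor(as_float)):
            raise ValueError(f"{path}: non-integer counts")
        values = as_float.astype(np.int64)
    if np.any(values < 0):
        raise ValueError(f"{path}: negative counts")
    if stage_order is not None:
        known = set(stage_order)
        for s in samples:
            if s.stage not in known:
                raise ValueError(f"{path}: stage {s.stage!r} not in configured stage order")
    return CountMatrix(list(df.index), samples, values)


def write_counts(path: str | Path, cm: CountMatrix, meta: str | None = None) -> None:
    with open(path, "w") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        fh.write("gene_id\t" + "\t".join(s.label for s in cm.samples) + "\n")
        for g, row in zip(cm.genes, cm.counts):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# BED intervals (chromatin marks)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a >=3-column BED file into a (chrom, start, end) DataFrame."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            rows.append((fields[0], int(fields[1]), int(fields[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed(path: str | Path, intervals: pd.DataFrame) -> None:
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_tsv(path: str | Path, df: pd.DataFrame, meta: str | None = None,
              index: bool = False) -> None:
    """Write an output table with an optional '#'-prefixed metadata line."""
    with open(path, "w") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        df.to_csv(fh, sep="\t", index=index)
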