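"""Readers, writers and shared domain containers.

Everything downstream operates on the types defined here: gene-by-sample
expression matrices with group labels, BED-style genomic intervals (0-based,
half-open), position weight matrices (PWMs), survival tables, and GO
annotations given as a gene-to-term map plus a parent-edge list.

All genomic coordinates are 0-based half-open internally.  1-based inclusive
coordinates appearing in external tables must be converted on ingestion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTN")
BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix (FPKM or probe intensity).

    ``values`` holds one row per gene and one column per sample; missing
    measurements are NaN, never silently zero-filled.  ``groups`` maps every
    sample id to a group name.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique())
            raise FormatError(f"duplicated gene ids: {dupes}")
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique())
            raise FormatError(f"duplicated sample ids: {dupes}")
        unlabeled = [s for s in cols if s not in self.groups]
        if unlabeled:
            raise FormatError(f"samples without a group label: {unlabeled}")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise FormatError("negative abundance values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        out = [s for s, g in self.groups.items() if g == group]
        if not out:
            raise KeyError(f"unknown group label: {group!r}")
        return [s for s in self.sample_ids if s in set(out)]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), dict(self.groups))


def _parse_group_map(group_map) -> dict[str, str]:
    if isinstance(group_map, dict):
        return dict(group_map)
    df = pd.read_csv(group_map, sep="\t", header=None, names=["sample", "group"],
                     dtype=str, comment="#")
    if df["sample"].duplicated().any():
        dupes = sorted(df.loc[df["sample"].duplicated(), "sample"])
        raise FormatError(f"duplicated sample ids in group map: {dupes}")
    return dict(zip(df["sample"], df["group"]))


def read_expression_tsv(path, group_map) -> ExpressionMatrix:
    """Read a TSV with gene ids in the first column and sample ids as header.

    Empty cells and the literal ``NA`` are flagged missing (NaN).  Any other
    non-numeric cell is a hard error naming the offending row and column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False, na_values=["", "NA"])
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[gene]][0]
        raise FormatError(
            f"non-numeric expression value {df.loc[gene, col]!r} "
            f"at gene {gene!r}, sample {col!r}")
    return ExpressionMatrix(numeric.astype(float), _parse_group_map(group_map))


def write_expression_tsv(matrix: ExpressionMatrix, path, group_path=None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene", na_rep="NA")
    if group_path is not None:
        pd.Series(matrix.groups).loc[matrix.sample_ids].to_csv(
            group_path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# genomic intervals (BED)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str = "+"
    name: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"interval {self.name!r} on {self.chrom}: start {self.start} "
                f">= end {self.end}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"invalid strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


def read_bed(path) -> list[GenomicInterval]:
    """Parse a BED file; the first 6 columns are honored, extras ignored."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{ln}: fewer than 3 BED columns")
            name = f[3] if len(f) > 3 else "."
            strand = f[5] if len(f) > 5 else "+"
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand, name))
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {name: upper-cased sequence}; alphabet {A,C,G,T,N}."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicated sequence id {rec.id!r}")
        s = str(rec.seq).upper()
        bad = set(s) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {rec.id!r} contains non-IUPAC-DNA characters {sorted(bad)}")
        seqs[rec.id] = s
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# motifs (MEME minimal format)
# ---------------------------------------------------------------------------

@dataclass
class MotifPWM:
    """Position weight matrix: L columns of (A, C, G, T) probabilities."""

    motif_id: str
    matrix: np.ndarray  # shape (L, 4)
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise FormatError(f"motif {self.motif_id!r}: matrix must be L x 4")
        if len(self) < 4:
            raise FormatError(f"motif {self.motif_id!r}: length {len(self)} < 4")
        if (self.matrix < 0).any():
            raise FormatError(f"motif {self.motif_id!r}: negative probabilities")
        sums = self.matrix.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise FormatError(
                f"motif {self.motif_id!r}: column sums deviate from 1 "
                f"(max |dev| {np.abs(sums - 1).max():.3g})")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "MotifPWM":
        return MotifPWM(self.motif_id, self.matrix[::-1, ::-1].copy(),
                        self.pseudocount)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def information_content(self, background=None) -> np.ndarray:
        """Per-column information content in bits."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        p = np.clip(self.matrix, 1e-12, None)
        return (p * np.log2(p / bg)).sum(axis=1)


def normalize_pwm(motif_id, raw, pseudocount: float = 1e-4) -> MotifPWM:
    """Build a MotifPWM from a raw (possibly unnormalized) L x 4 array.

    A pseudocount is added to every cell and columns are renormalized to sum
    to 1.  Columns whose raw sum deviates from 1 by more than 0.01 trigger a
    warning (they usually indicate a truncated or mis-parsed matrix).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 4:
        raise FormatError(f"motif {motif_id!r}: expected L x 4 probabilities")
    sums = raw.sum(axis=1)
    if np.abs(sums - 1.0).max() > 0.01:
        warnings.warn(
            f"motif {motif_id!r}: column sums deviate from 1 by up to "
            f"{np.abs(sums - 1).max():.3g}; renormalizing", stacklevel=2)
    mat = raw + pseudocount
    mat = mat / mat.sum(axis=1, keepdims=True)
    return MotifPWM(motif_id, mat, pseudocount)


def read_meme_minimal(path, pseudocount: float = 1e-4) -> list[MotifPWM]:
    """Parse MEME minimal motif format into a list of MotifPWM.

    Only the letter-probability matrices are used; columns are renormalized
    to sum to 1 after adding ``pseudocount``.
    """
    motifs: list[MotifPWM] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: MOTIF line without an identifier")
            motif_id = parts[1]
            # seek the letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith(
                    "letter-probability matrix"):
                if lines[j].strip().startswith("MOTIF"):
                    raise FormatError(
                        f"{path}: motif {motif_id!r} has no letter-probability matrix")
                j += 1
            if j == len(lines):
                raise FormatError(
                    f"{path}: motif {motif_id!r} has no letter-probability matrix")
            rows = []
            j += 1
            while j < len(lines):
                stripped = lines[j].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                try:
                    row = [float(x) for x in stripped.split()]
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: malformed matrix row for motif {motif_id!r}: "
                        f"{stripped!r}") from exc
                if len(row) != 4:
                    raise FormatError(
                        f"{path}: motif {motif_id!r}: matrix row with "
                        f"{len(row)} columns (expected 4)")
                rows.append(row)
                j += 1
            motifs.append(normalize_pwm(motif_id, np.array(rows), pseudocount))
            i = j
        else:
            i += 1
    return motifs


def write_meme_minimal(motifs, path, background=None) -> None:
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg))
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(m)} "
                     f"nsites= 20 E= 0\n")
            for row in m.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# survival tables
# ---------------------------------------------------------------------------

SURVIVAL_META = ["patient_id", "time", "event", "diploid"]


def read_survival_tsv(path) -> pd.DataFrame:
    """Read a survival table: patient_id, time, event, diploid, then one
    column of expression per gene."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SURVIVAL_META if c not in df.columns]
    if missing:
        raise FormatError(f"survival table missing columns: {missing}")
    if df["patient_id"].duplicated().any():
        dupes = sorted(df.loc[df["patient_id"].duplicated(), "patient_id"])
        raise FormatError(f"duplicated patient ids: {dupes}")
    if (df["time"] < 0).any():
        raise FormatError("negative survival times")
    if not df["event"].isin([0, 1]).all():
        raise FormatError("event indicator must be 0/1")
    if not df["diploid"].isin([0, 1]).all():
        raise FormatError("diploid flag must be 0/1")
    return df


def write_survival_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------

@dataclass
class GOAnnotation:
    """Gene-to-term annotation plus is_a parent edges (child -> parents)."""

    gene2terms: dict[str, set] = field(default_factory=dict)
    term_parents: dict[str, set] = field(default_factory=dict)

    def terms(self) -> set:
        out = set(self.term_parents)
        for parents in self.term_parents.values():
            out |= parents
        for ts in self.gene2terms.values():
            out |= ts
        return out


def read_go_annotation(gene2term_path, edges_path=None) -> GOAnnotation:
    """Read a two-column gene->term TSV and an optional child->parent TSV."""
    g2t = pd.read_csv(gene2term_path, sep="\t", header=None,
                      names=["gene", "term"], dtype=str, comment="#")
    gene2terms: dict[str, set] = {}
    for gene, term in zip(g2t["gene"], g2t["term"]):
        gene2terms.setdefault(gene, set()).add(term)
    term_parents: dict[str, set] = {}
    if edges_path is not None:
        edges = pd.read_csv(edges_path, sep="\t", header=None,
                            names=["child", "parent"], dtype=str, comment="#")
        for child, parent in zip(edges["child"], edges["parent"]):
            term_parents.setdefault(child, set()).add(parent)
    return GOAnnotation(gene2terms, term_parents)


def write_go_annotation(annotation: GOAnnotation, gene2term_path, edges_path) -> None:
    with open(gene2term_path, "w") as fh:
        for gene in sorted(annotation.gene2terms):
            for term in sorted(annotation.gene2terms[gene]):
                fh.write(f"{gene}\t{term}\n")
    with open(edges_path, "w") as fh:
        for child in sorted(annotation.term_parents):
            for parent in sorted(annotation.term_parents[child]):
                fh.write(f"{child}\t{parent}\n")
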