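"""Input/output for the standard formats the 5gmC pipeline touches.

External dialects are converted at the boundary to a single internal
convention: 0-based half-open intervals for all genomic ranges.  Cytosine
positions keep the 1-based reference coordinate of the Bismark CX-report
dialect (``pos``), with ``pos - 1`` used whenever a position enters interval
arithmetic.  Minus-strand cytosines are independent records; symmetric CpG
counts are never pooled.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "GenomeRef",
    "CytosineRecord",
    "GeneModel",
    "IntervalSet",
    "ExpressionRecord",
    "CytosineReportError",
    "read_cytosine_report",
    "read_cytosine_table",
    "write_cytosine_table",
    "records_to_table",
    "table_to_records",
    "read_gff_genes",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "read_expression_table",
    "read_de_table",
    "CX_COLUMNS",
]

#: Column order of the tab-separated per-cytosine report (CX-report dialect).
CX_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "n_unconverted",
    "n_converted",
    "context",
    "trinucleotide",
]

VALID_CONTEXTS = frozenset({"CG", "CHG", "CHH", "AMBIG"})


class CytosineReportError(ValueError):
    """Malformed per-cytosine report line (carries the offending line number)."""


@dataclass
class GenomeRef:
    """A reference genome held in memory as uppercase sequences.

    Stands for any reference, including synthetic ones; chromosome names
    must be unique and the alphabet is restricted to A/C/G/T/N.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        allowed = set("ACGTN")
        for name, seq in self.sequences.items():
            seq = seq.upper()
            extra = set(seq) - allowed
            if extra:
                raise ValueError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(extra)}"
                )
            self.sequences[name] = seq

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def gc_fraction(self) -> float:
        gc = total = 0
        for seq in self.sequences.values():
            gc += seq.count("G") + seq.count("C")
            total += len(seq) - seq.count("N")
        return gc / total if total else float("nan")

    @classmethod
    def from_fasta(cls, path) -> "GenomeRef":
        from Bio import SeqIO

        seqs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate chromosome name {rec.id!r} in FASTA")
            seqs[rec.id] = str(rec.seq).upper()
        return cls(seqs)

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class CytosineRecord:
    """One strand-specific cytosine with conversion counts.

    ``n_unconverted`` is the count of reads showing C (the candidate
    modification under the sample's chemistry) and ``n_converted`` the count
    of reads showing T.  ``pos`` is the 1-based reference (plus-strand)
    coordinate, as emitted by per-cytosine methylation extractors.
    """

    chrom: str
    pos: int
    strand: str
    n_unconverted: int
    n_converted: int
    context: str
    trinucleotide: str

    @property
    def depth(self) -> int:
        return self.n_unconverted + self.n_converted

    @property
    def ratio(self) -> float:
        d = self.depth
        return self.n_unconverted / d if d else float("nan")


def _parse_cx_line(line: str, lineno: int) -> CytosineRecord:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < len(CX_COLUMNS):
        missing = CX_COLUMNS[len(parts)]
        raise CytosineReportError(
            f"line {lineno}: expected {len(CX_COLUMNS)} tab-separated columns, "
            f"got {len(parts)} (missing column {len(parts) + 1}, {missing!r})"
        )
    chrom, pos_s, strand, n_unc_s, n_con_s, context, tri = parts[:7]
    try:
        pos = int(pos_s)
        n_unc = int(n_unc_s)
        n_con = int(n_con_s)
    except ValueError as exc:
        raise CytosineReportError(f"line {lineno}: non-integer count field: {exc}") from None
    if n_unc < 0 or n_con < 0:
        raise CytosineReportError(f"line {lineno}: negative count ({n_unc}, {n_con})")
    if strand not in ("+", "-"):
        raise CytosineReportError(f"line {lineno}: strand must be '+' or '-', got {strand!r}")
    return CytosineRecord(chrom, pos, strand, n_unc, n_con, context, tri)


def read_cytosine_report(path) -> Iterator[CytosineRecord]:
    """Stream records from a tab-separated per-cytosine conversion report.

    Columns: chrom, 1-based position, strand, count of unconverted (C) reads,
    count of converted (T) reads, context, trinucleotide.  Malformed lines
    raise :class:`CytosineReportError` naming the line number and column.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            yield _parse_cx_line(line, lineno)


def records_to_table(records: Iterable[CytosineRecord]) -> pd.DataFrame:
    rows = [
        (r.chrom, r.pos, r.strand, r.n_unconverted, r.n_converted, r.context, r.trinucleotide)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=CX_COLUMNS)
    return _finalize_table(df)


def _finalize_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.astype(
        {"pos": np.int64, "n_unconverted": np.int64, "n_converted": np.int64},
        errors="raise",
    )
    df["depth"] = df["n_unconverted"] + df["n_converted"]
    with np.errstate(invalid="ignore"):
        df["ratio"] = np.where(df["depth"] > 0, df["n_unconverted"] / df["depth"], np.nan)
    return df


def read_cytosine_table(path) -> pd.DataFrame:
    """Read a whole per-cytosine report into a DataFrame (columnar form).

    Adds derived ``depth`` and ``ratio`` columns.  Validation matches the
    streaming reader.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            names=CX_COLUMNS,
            header=None,
            dtype={"chrom": str, "strand": str, "context": str, "trinucleotide": str},
            comment=None,
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=CX_COLUMNS)
    if df.shape[1] < len(CX_COLUMNS) or (
        len(df) and df["trinucleotide"].isna().any()
    ):
        # fall back to the line parser for a precise error message
        for _ in read_cytosine_report(path):
            pass
    if len(df) and ((df["n_unconverted"] < 0).any() or (df["n_converted"] < 0).any()):
        bad = df.index[(df["n_unconverted"] < 0) | (df["n_converted"] < 0)][0]
        raise CytosineReportError(f"line {bad + 1}: negative count")
    return _finalize_table(df)


def write_cytosine_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=CX_COLUMNS)


def table_to_records(df: pd.DataFrame) -> Iterator[CytosineRecord]:
    for row in df.itertuples(index=False):
        yield CytosineRecord(
            row.chrom, int(row.pos), row.strand,
            int(row.n_unconverted), int(row.n_converted),
            row.context, row.trinucleotide,
        )


# ---------------------------------------------------------------------------
# Gene models


@dataclass
class GeneModel:
    """One gene represented by its single (longest) transcript.

    Coordinates are internal 0-based half-open on the plus strand of the
    reference; ``strand`` records transcription orientation.  Introns are the
    gaps between consecutive exons.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"gene {self.gene_id}: exon [{s},{e}) outside gene span "
                    f"[{self.start},{self.end})"
                )
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """0-based position of the transcription end site base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


class GffStructureError(ValueError):
    """Structurally inconsistent gene annotation (e.g. exon outside parent)."""


def read_gff_genes(path) -> list[GeneModel]:
    """Load gene models from GFF3, keeping the longest transcript per gene.

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    Transcript length is the summed exon length (gene span when a transcript
    has no exon children).  An exon outside its parent transcript span raises
    :class:`GffStructureError`.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best = None  # (exonic_length, transcript_id, exons, span)
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript")))
        if not transcripts:
            transcripts = [gene]
        for tx in transcripts:
            tx_start, tx_end = tx.start - 1, tx.end
            exons = []
            for ex in db.children(tx, featuretype="exon"):
                s, e = ex.start - 1, ex.end
                if s < tx_start or e > tx_end:
                    raise GffStructureError(
                        f"exon [{ex.start},{ex.end}] outside transcript {tx.id} "
                        f"span [{tx.start},{tx.end}]"
                    )
                exons.append((s, e))
            if not exons:
                exons = [(tx_start, tx_end)]
            exonic = sum(e - s for s, e in exons)
            key = (exonic, tx.id)
            if best is None or key > best[0]:
                best = (key, exons, (tx_start, tx_end))
        (_, _), exons, (span_s, span_e) = best[0], best[1], best[2]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=span_s,
                end=span_e,
                exons=sorted(exons),
            )
        )
    return genes


def write_gff_genes(genes: list[GeneModel], path) -> None:
    """Write gene models as minimal GFF3 (gene/mRNA/exon, 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            base = f"{g.chrom}\tdeaseq\t"
            tail = f"\t.\t{g.strand}\t."
            fh.write(f"{base}gene\t{g.start + 1}\t{g.end}{tail}\tID={g.gene_id}\n")
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{base}mRNA\t{g.start + 1}\t{g.end}{tail}\tID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{base}exon\t{s + 1}\t{e}{tail}\tID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# Interval sets (TEs, histone marks)


@dataclass
class IntervalSet:
    """Named collection of 0-based half-open genomic intervals."""

    label: str
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, ivs in self.intervals.items():
            for s, e in ivs:
                if not s < e:
                    raise ValueError(f"{self.label}: empty interval [{s},{e}) on {chrom}")
            self.intervals[chrom] = sorted(tuple(iv) for iv in ivs)

    def merged(self) -> "IntervalSet":
        """Union of overlapping or touching intervals, per chromosome."""
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in self.intervals.items():
            merged: list[list[int]] = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out[chrom] = [(s, e) for s, e in merged]
        return IntervalSet(self.label, out)

    def total_length(self) -> int:
        m = self.merged()
        return sum(e - s for ivs in m.intervals.values() for s, e in ivs)

    def contains_points(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Vectorized point-in-interval test for 0-based positions.

        Intervals are merged first, so the test is well defined even for
        overlapping input intervals.
        """
        pos0 = np.asarray(pos0)
        ivs = self.merged().intervals.get(chrom, [])
        if not ivs:
            return np.zeros(pos0.shape, dtype=bool)
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        idx = np.searchsorted(starts, pos0, side="right") - 1
        inside = idx >= 0
        inside[inside] &= pos0[inside] < ends[idx[inside]]
        return inside

    @classmethod
    def from_bed(cls, path, label: str | None = None) -> "IntervalSet":
        df = read_bed(path)
        ivs: dict[str, list[tuple[int, int]]] = {}
        for row in df.itertuples(index=False):
            ivs.setdefault(row.chrom, []).append((int(row.start), int(row.end)))
        if label is None:
            label = str(df["name"].iloc[0]) if "name" in df.columns and len(df) else "intervals"
        return cls(label, ivs)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for s, e in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{self.label}\n")


def read_bed(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names[:3])
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Expression / differential-expression tables


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    fpkm: float
    de_status: str | None = None  # {"up", "down", "ns"} when a DE table is loaded
    log2fc: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.fpkm) or self.fpkm < 0:
            raise ValueError(f"{self.gene_id}: FPKM must be finite and >= 0")


def read_expression_table(path) -> pd.DataFrame:
    """Read a two-column gene-id / FPKM table (TSV, header optional)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "fpkm"])
    df["fpkm"] = df["fpkm"].astype(float)
    if (~np.isfinite(df["fpkm"])).any() or (df["fpkm"] < 0).any():
        raise ValueError("FPKM values must be finite and >= 0")
    return df[["gene_id", "fpkm"]]


def read_de_table(path) -> pd.DataFrame:
    """Read a differential-expression call table: gene_id, status[, log2fc]."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        names = ["gene_id", "status", "log2fc"]
        df = pd.read_csv(path, sep="\t", header=None)
        df.columns = names[: df.shape[1]]
    bad = set(df["status"]) - {"up", "down", "ns"}
    if bad:
        raise ValueError(f"unknown DE status values: {sorted(bad)}")
    return df


# ---------------------------------------------------------------------------
# bedGraph


def write_bedgraph(sites: pd.DataFrame, value_field: str, path) -> None:
    """Write single-cytosine sites as a bedGraph track.

    ``sites`` must carry 1-based ``pos`` and be sorted by (chrom, pos);
    output lines are 0-based half-open with the value rounded to 4 decimals.
    """
    if value_field not in sites.columns:
        raise KeyError(f"value field {value_field!r} not in site table")
    if len(sites):
        chroms = sites["chrom"].to_numpy()
        pos = sites["pos"].to_numpy()
        # chromosome blocks must be contiguous and positions non-decreasing
        seen: set = set()
        prev = None
        for c in chroms:
            if c != prev:
                if c in seen:
                    raise ValueError("bedGraph input not sorted: chromosome blocks split")
                seen.add(c)
                prev = c
        breaks = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        for block in np.split(pos, breaks):
            if np.any(np.diff(block) < 0):
                raise ValueError("bedGraph input not sorted by position")
    with open(path, "w") as fh:
        for row in sites.itertuples(index=False):
            p = int(getattr(row, "pos"))
            v = float(getattr(row, value_field))
            fh.write(f"{getattr(row, 'chrom')}\t{p - 1}\t{p}\t{v:.4f}\n")


def read_bedgraph(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    return df
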