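"""Domain types and readers/writers for the formats the pipeline touches.

Coordinate convention is globally 0-based, half-open (UCSC BED semantics):
an interval ``[start, end)`` covers ``end - start`` bases.  Softmasked
(lowercase) FASTA is the sole repeat encoding.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


VALID_STRANDS = ("+", "-", ".")
_FASTA_ALPHABET = set("ACGTNacgtn")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic region, optionally stranded and named."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class ReadAlignmentSet:
    """Strand-aware aligned reads plus the library size used for rpm scaling.

    ``total_mapped`` is the total number of mapped reads in the library and
    may exceed ``len(reads)`` when only a chromosome subset is held.
    """

    reads: list[GenomicInterval]
    total_mapped: int

    def __post_init__(self) -> None:
        if self.total_mapped < 1:
            raise ValidationError("total_mapped must be >= 1")


@dataclass
class CoverageTrack:
    """Per-chromosome sorted, non-overlapping (start, end, value) intervals.

    bedGraph semantics: bases not covered by any interval have value 0.
    """

    intervals: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, ivs in self.intervals.items():
            prev_end = -1
            for start, end, value in ivs:
                if start < prev_end:
                    raise ValidationError(
                        f"overlapping bedGraph intervals on {chrom} near {start}"
                    )
                if start >= end:
                    raise ValidationError(f"empty bedGraph interval on {chrom} at {start}")
                if not np.isfinite(value):
                    raise ValidationError(f"non-finite bedGraph value on {chrom} at {start}")
                prev_end = end

    def mean_over(self, region: GenomicInterval) -> float:
        """Base-weighted mean value over *region*; uncovered bases count as 0."""
        ivs = self.intervals.get(region.chrom, [])
        if not ivs:
            return 0.0
        starts = [iv[0] for iv in ivs]
        total = 0.0
        # first interval that could overlap: the one before the insertion point
        i = max(0, bisect_right(starts, region.start) - 1)
        for start, end, value in ivs[i:]:
            if start >= region.end:
                break
            overlap = min(end, region.end) - max(start, region.start)
            if overlap > 0:
                total += value * overlap
        return total / region.length()


@dataclass
class GenomeSequence:
    """chromosome -> sequence over {A,C,G,T,N} with lowercase = softmasked."""

    chroms: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chroms.items():
            bad = set(seq) - _FASTA_ALPHABET
            if bad:
                raise ValidationError(
                    f"unknown base character(s) {sorted(bad)} in chromosome {name}"
                )

    def fetch(self, region: GenomicInterval) -> str:
        seq = self.chroms.get(region.chrom)
        if seq is None:
            raise ValidationError(f"unknown chromosome {region.chrom}")
        if region.end > len(seq):
            raise ValidationError(
                f"region {region.chrom}:{region.start}-{region.end} beyond "
                f"chromosome end ({len(seq)})"
            )
        return seq[region.start : region.end]


@dataclass(frozen=True)
class TssAnnotation:
    """A transcription start site: single 0-based base position."""

    gene: str
    chrom: str
    position: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValidationError(f"TSS position must be >= 0 for gene {self.gene}")


@dataclass
class ExpressionTable:
    """gene id -> RPKM (non-negative, finite)."""

    rpkm: dict[str, float]

    def __post_init__(self) -> None:
        for gene, value in self.rpkm.items():
            if not np.isfinite(value) or value < 0:
                raise ValidationError(f"invalid RPKM {value!r} for gene {gene}")

    def get(self, gene: str, default: float = 0.0) -> float:
        return self.rpkm.get(gene, default)


@dataclass
class PWM:
    """Position weight matrix: L rows of base probabilities in A,C,G,T order."""

    motif_id: str
    matrix: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValidationError(f"PWM {self.motif_id}: matrix must be L x 4")
        if np.any(self.matrix <= 0):
            raise ValidationError(f"PWM {self.motif_id}: entries must be > 0 after pseudocount")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValidationError(f"PWM {self.motif_id}: rows must each sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]


class FeatureMatrix:
    """Rows = constituents, columns = named features, optional binary labels.

    Labels follow the SE/TE convention: 1 = SE constituent (positive class),
    0 = TE constituent.  Backed by a pandas DataFrame; values must be finite.
    """

    LABEL_COLUMN = "label"

    def __init__(
        self,
        values: pd.DataFrame,
        labels: Sequence[int] | None = None,
    ) -> None:
        if values.index.has_duplicates:
            raise ValidationError("row ids must be unique")
        if values.columns.has_duplicates:
            raise ValidationError("feature names must be unique")
        if self.LABEL_COLUMN in values.columns:
            raise ValidationError(f"{self.LABEL_COLUMN!r} is reserved; pass labels separately")
        arr = values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValidationError("feature values must be finite")
        self.values = values.astype(float)
        if labels is not None:
            labels = np.asarray(labels, dtype=int)
            if len(labels) != len(values):
                raise ValidationError("label vector length must equal row count")
            if labels.size and not set(np.unique(labels)) <= {0, 1}:
                raise ValidationError("labels must be in {0, 1}")
        self.labels = labels

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        if (self.labels is None) != (other.labels is None):
            return False
        if self.labels is not None and not np.array_equal(self.labels, other.labels):
            return False
        return self.values.equals(other.values)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_bed(path, dialect: str = "regions") -> list[GenomicInterval]:
    """Read BED intervals.

    ``dialect='regions'`` accepts BED3+ (name from column 4 if present);
    ``dialect='reads6'`` requires BED6 with a strand in column 6.
    Coordinates are taken verbatim (already 0-based half-open in BED).
    """
    if dialect not in ("regions", "reads6"):
        raise ValueError(f"unknown BED dialect {dialect!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = "."
            if dialect == "reads6":
                if len(fields) < 6:
                    raise ParseError(f"{path}:{lineno}: reads6 requires 6 columns")
                strand = fields[5]
                if strand not in ("+", "-"):
                    raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            try:
                out.append(
                    GenomicInterval(fields[0], start, end, strand=strand, name=name)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_fasta(path) -> GenomeSequence:
    """Read a (possibly softmasked) FASTA file, preserving case."""
    chroms: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chroms:
            raise ValidationError(f"duplicate chromosome {record.id} in {path}")
        chroms[record.id] = str(record.seq)
    return GenomeSequence(chroms)


def write_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bedgraph(path) -> CoverageTrack:
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph requires 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed bedGraph record") from exc
            intervals.setdefault(fields[0], []).append((start, end, value))
    for ivs in intervals.values():
        ivs.sort(key=lambda t: t[0])
    return CoverageTrack(intervals)


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, ivs in track.intervals.items():
            for start, end, value in ivs:
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def read_pwm_transfac(path, pseudocount: float = 1.0) -> list[PWM]:
    """Read TRANSFAC-style count matrices, normalized with a pseudocount.

    Per position: p_b = (count_b + pseudocount) / (sum_counts + 4*pseudocount).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    pwms: list[PWM] = []
    motif_id: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal motif_id, rows
        if motif_id is not None and rows:
            counts = np.asarray(rows, dtype=float)
            probs = (counts + pseudocount) / (
                counts.sum(axis=1, keepdims=True) + 4 * pseudocount
            )
            pwms.append(PWM(motif_id, probs, pseudocount=pseudocount))
        motif_id, rows = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            tag = line[:2]
            if tag in ("ID", "NA") and motif_id is None:
                motif_id = line.split(None, 1)[1].strip() if len(line.split()) > 1 else ""
            elif tag == "AC" and motif_id is None:
                motif_id = line.split(None, 1)[1].strip()
            elif tag == "//":
                flush()
            elif line[:1].isdigit() and motif_id is not None:
                parts = line.split()
                try:
                    rows.append([float(x) for x in parts[1:5]])
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric matrix cell") from exc
    flush()
    return pwms


def read_expression_tsv(path) -> ExpressionTable:
    """Read a 2-column (gene, RPKM) TSV; a header line is tolerated."""
    rpkm: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                value = float(fields[1])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ParseError(f"{path}:{lineno}: non-numeric RPKM") from None
            rpkm[fields[0]] = value
    return ExpressionTable(rpkm)


def write_expression_tsv(expr: ExpressionTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\trpkm\n")
        for gene, value in expr.rpkm.items():
            fh.write(f"{gene}\t{value:.6f}\n")


def write_tss_bed(tss: Iterable[TssAnnotation], path) -> None:
    """TSS as single-base BED6 records (gene id in the name column)."""
    with open(path, "w") as fh:
        for t in tss:
            fh.write(f"{t.chrom}\t{t.position}\t{t.position + 1}\t{t.gene}\t0\t{t.strand}\n")


def read_tss_bed(path) -> list[TssAnnotation]:
    out = []
    seen: set[str] = set()
    for iv in read_bed(path, dialect="regions"):
        gene = iv.name or f"{iv.chrom}:{iv.start}"
        if gene in seen:
            raise ValidationError(f"duplicate gene id {gene} in {path}")
        seen.add(gene)
        out.append(TssAnnotation(gene, iv.chrom, iv.start, strand=iv.strand))
    return out


def write_feature_matrix(m: FeatureMatrix, path) -> None:
    """TSV with a header of feature names and a reserved ``label`` column.

    Values are written at fixed 6-decimal precision so that a write/read
    round trip is bitwise-stable on the text representation.
    """
    df = m.values.copy()
    if m.labels is not None:
        df[FeatureMatrix.LABEL_COLUMN] = m.labels
    df.to_csv(path, sep="\t", float_format="%.6f", index_label="id")


def read_feature_matrix(path) -> FeatureMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    labels = None
    if FeatureMatrix.LABEL_COLUMN in df.columns:
        labels = df.pop(FeatureMatrix.LABEL_COLUMN).to_numpy(dtype=int)
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise ValidationError(f"{path}: non-numeric matrix cell")
    return FeatureMatrix(df, labels=labels)
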