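"""Readers/writers for the standard formats the pipeline touches.

Internal convention everywhere: 0-based, half-open intervals. Conversion to
the 1-based inclusive GTF convention (and back) happens only at the I/O
boundary. BED output is emitted 0-based half-open, as the format requires.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Gene",
    "GenomeAnnotation",
    "TranscriptModel",
    "AlignmentHit",
    "SampleMeta",
    "ExpressionMatrix",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "write_annotation_gtf",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "extract_sequence",
    "read_expression_table",
    "write_expression_table",
    "write_sample_metadata",
    "read_blast_tabular",
]


class GtfParseError(ValueError):
    """Malformed GTF input; message names the offending line."""


@dataclass(frozen=True)
class Gene:
    """One annotated gene locus (0-based half-open interval)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GenomeAnnotation:
    """Annotated genes plus (optionally) chromosome lengths."""

    genes: list[Gene]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            L = self.chrom_lengths.get(g.chrom)
            if L is not None and g.end > L:
                raise ValueError(
                    f"gene {g.gene_id} extends past end of {g.chrom} ({g.end} > {L})"
                )

    def genes_by_chrom(self, biotype: str | None = None) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            if biotype is not None and g.biotype != biotype:
                continue
            out.setdefault(g.chrom, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: (g.start, g.end))
        return out


@dataclass
class TranscriptModel:
    """An assembled transcript: exon chain plus optional spliced sequence.

    ``exons`` are 0-based half-open intervals, sorted, non-overlapping.
    ``sequence`` (when set) is the spliced, strand-oriented nucleotide string.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if not 0 <= s < e:
                raise ValueError(f"{self.transcript_id}: bad exon [{s},{e})")
            if s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= summed exon length {self.length}"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment hit; percent_identity is a fraction in [0,1]."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: float
    e_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 1.0:
            raise ValueError(f"identity {self.percent_identity} outside [0,1]")
        if self.align_length < 1:
            raise ValueError("align_length < 1")
        if self.e_value < 0:
            raise ValueError("negative e_value")


@dataclass
class SampleMeta:
    sample_id: str
    tissue: str | None = None
    time_days: float | None = None
    time_rank: int | None = None
    stage: str | None = None


class ExpressionMatrix:
    """FPKM values (features x samples) plus per-sample metadata.

    ``feature_kind`` maps feature -> "lincRNA" | "mRNA"; it is assigned from
    pipeline output, not read from the file.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: Sequence[SampleMeta],
        feature_kind: Mapping[str, str] | None = None,
    ):
        by_id = {m.sample_id: m for m in samples}
        missing = [c for c in values.columns if c not in by_id]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        if (values.values < 0).any():
            raise ValueError("negative FPKM values")
        if values.isna().any().any():
            raise ValueError("missing FPKM values")
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature IDs: {dups}")
        ranks = sorted(
            m.time_rank for m in samples if m.time_rank is not None
        )
        if ranks and ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(f"time_rank values {ranks} are not a permutation of 1..n")
        self.values = values
        self.samples = [by_id[c] for c in values.columns]
        self.feature_kind = dict(feature_kind or {})

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def sample_attr(self, name: str) -> list:
        return [getattr(m, name) for m in self.samples]

    def subset(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [f for f in feature_ids if f in self.values.index]
        return ExpressionMatrix(self.values.loc[ids], self.samples, self.feature_kind)


# ---------------------------------------------------------------------------
# GTF


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _parse_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(" ", 1)
        except ValueError:
            raise GtfParseError(f"line {lineno}: malformed attribute {chunk!r}")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path) -> tuple[GenomeAnnotation, list[TranscriptModel]]:
    """Read a GTF file into an annotation plus transcript models.

    ``gene`` features populate the annotation; ``exon`` features, grouped by
    transcript_id, populate the transcripts. Coordinates are converted from
    GTF's 1-based inclusive convention to 0-based half-open.
    """
    genes: list[Gene] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, tuple[str, str]] = {}
    n_records = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, raw = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates")
            if end1 < start1:
                raise ValueError(f"line {lineno}: end < start ({end1} < {start1})")
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _parse_attributes(raw, lineno)
            n_records += 1
            if feature == "gene":
                gid = attrs.get("gene_id")
                if gid is None:
                    raise GtfParseError(f"line {lineno}: gene record lacks gene_id")
                genes.append(
                    Gene(
                        gene_id=gid,
                        chrom=chrom,
                        strand=strand,
                        start=start,
                        end=end,
                        biotype=attrs.get("gene_biotype", "protein_coding"),
                    )
                )
            elif feature == "exon":
                tid = attrs.get("transcript_id")
                if tid is None:
                    raise GtfParseError(f"line {lineno}: exon record lacks transcript_id")
                exons.setdefault(tid, []).append((start, end))
                tx_meta.setdefault(tid, (chrom, strand))
            # transcript/CDS/other feature rows carry no extra information we use
    if n_records == 0:
        warnings.warn(f"{path}: empty GTF", stacklevel=2)
    transcripts = []
    for tid in exons:
        chrom, strand = tx_meta[tid]
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                exons=sorted(exons[tid]),
            )
        )
    transcripts.sort(key=lambda t: t.transcript_id)
    return GenomeAnnotation(genes=genes), transcripts


def write_gtf(transcripts: Iterable[TranscriptModel], path, source: str = "lincscan") -> None:
    """Write transcripts as GTF (1-based inclusive), one transcript + exon rows each."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.transcript_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def write_annotation_gtf(annotation: GenomeAnnotation, path, source: str = "lincscan") -> None:
    with open(path, "w") as fh:
        for g in annotation.genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_bed(transcripts: Iterable[TranscriptModel], path) -> None:
    """BED6 export of transcript spans (already 0-based half-open)."""
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.transcript_id}\t0\t{t.strand}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def extract_sequence(genome: Mapping[str, str], transcript: TranscriptModel) -> str:
    """Spliced, strand-oriented, uppercase sequence of a transcript.

    Unstranded ('.') transcripts are treated as '+'; downstream ORF and
    hexamer scans cover both strands anyway.
    """
    if transcript.chrom not in genome:
        raise KeyError(f"chromosome {transcript.chrom!r} not in genome")
    chrom_seq = genome[transcript.chrom]
    if transcript.end > len(chrom_seq):
        raise ValueError(
            f"{transcript.transcript_id}: exon interval exceeds {transcript.chrom} "
            f"length {len(chrom_seq)}"
        )
    spliced = "".join(chrom_seq[s:e] for s, e in transcript.exons).upper()
    if transcript.strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
    return spliced


# ---------------------------------------------------------------------------
# Expression tables


def read_expression_table(path, metadata_path) -> ExpressionMatrix:
    """Read an FPKM TSV (features x samples) plus a sample-metadata TSV."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ValueError("metadata lacks a sample_id column")
    samples = []
    for row in meta.itertuples(index=False):
        d = row._asdict()
        samples.append(
            SampleMeta(
                sample_id=d["sample_id"],
                tissue=_opt(d.get("tissue")),
                time_days=None if pd.isna(d.get("time_days")) else float(d["time_days"]),
                time_rank=None if pd.isna(d.get("time_rank")) else int(d["time_rank"]),
                stage=_opt(d.get("stage")),
            )
        )
    return ExpressionMatrix(values, samples)


def _opt(v):
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
        return None
    return str(v)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t")


def write_sample_metadata(samples: Sequence[SampleMeta], path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "tissue": m.tissue or "",
            "time_days": "" if m.time_days is None else m.time_days,
            "time_rank": "" if m.time_rank is None else m.time_rank,
            "stage": m.stage or "",
        }
        for m in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BLAST tabular


def read_blast_tabular(path) -> list[AlignmentHit]:
    """Read 12-column tabular alignment output (qseqid..bitscore).

    Percent identity is rescaled from the 0-100 scale to a [0,1] fraction.
    Row order is preserved.
    """
    hits: list[AlignmentHit] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"line {lineno}: expected 12 columns, got {len(fields)}"
                )
            (qid, sid, pident, length, _mm, _gaps, qs, qe, ss, se, evalue, bits) = fields
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=sid,
                    percent_identity=float(pident) / 100.0,
                    align_length=int(length),
                    q_start=int(qs),
                    q_end=int(qe),
                    s_start=int(ss),
                    s_end=int(se),
                    score=float(bits),
                    e_value=float(evalue),
                )
            )
    return hits
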