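"""The lincRNA identification cascade.

Candidate transcripts run through an ordered chain of filters — minimum
length, intergenic position (with a flank buffer around protein-coding
genes), coding-potential score, maximum ORF length, housekeeping-RNA
similarity, and redundancy clustering — with every removal recorded in a
FilterReport so the cascade is fully auditable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .hexamer import hexamer_log_ratios
from .io_formats import (
    AlignmentHit,
    GenomeAnnotation,
    TranscriptModel,
    extract_sequence,
)

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FRAME_ORDER = ("+1", "+2", "+3", "-1", "-2", "-3")

DEFAULT_PARAMS = {
    "min_length": 200,
    "orf_max": 100,
    "flank_bp": 500,
    "hk_evalue": 1e-5,
    "cluster_identity": 0.95,
}


@dataclass
class OrfResult:
    transcript_id: str
    longest_orf_aa: int
    frame: str
    orf_start: int
    orf_end: int


@dataclass
class CodingScore:
    transcript_id: str
    score: float

    @property
    def label(self) -> str:
        return "coding" if self.score > 0 else "noncoding"


@dataclass
class Cluster:
    representative_id: str
    member_ids: set[str]
    identities: dict[str, float]


@dataclass
class FilterReport:
    """Audit trail of the cascade: per-stage survivors and removals."""

    stage_names: list[str] = field(default_factory=list)
    surviving_ids: dict[str, set[str]] = field(default_factory=dict)
    removed: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    params: dict[str, float] = field(default_factory=dict)

    def record(self, stage: str, survivors: set[str], removed: set[tuple[str, str]]):
        self.stage_names.append(stage)
        self.surviving_ids[stage] = set(survivors)
        self.removed[stage] = set(removed)

    def validate(self) -> None:
        """Check the subset/partition invariants between consecutive stages."""
        for prev, cur in zip(self.stage_names, self.stage_names[1:]):
            before = self.surviving_ids[prev]
            after = self.surviving_ids[cur]
            removed_ids = {tid for tid, _ in self.removed[cur]}
            if not after <= before:
                raise AssertionError(f"stage {cur}: survivors not a subset of {prev}")
            if after | removed_ids != before or (after & removed_ids):
                raise AssertionError(f"stage {cur}: removed+survivors do not partition input")

    def counts(self) -> dict[str, int]:
        return {s: len(self.surviving_ids[s]) for s in self.stage_names}

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tsurviving\tremoved\n")
            for s in self.stage_names:
                fh.write(f"{s}\t{len(self.surviving_ids[s])}\t{len(self.removed[s])}\n")


# ---------------------------------------------------------------------------
# Individual filters


def filter_length(
    transcripts: Sequence[TranscriptModel], min_length: int = 200
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Keep transcripts whose summed exon length is >= min_length."""
    kept = [t for t in transcripts if t.length >= min_length]
    dropped = [t for t in transcripts if t.length < min_length]
    return kept, dropped


def classify_intergenic(
    transcripts: Sequence[TranscriptModel],
    annotation: GenomeAnnotation,
    flank_bp: int = 500,
    biotype: str | None = "protein_coding",
) -> tuple[list[TranscriptModel], list[tuple[TranscriptModel, str]]]:
    """Keep transcripts whose genomic span is clear of every gene ± flank.

    Overlap is strand-blind half-open interval intersection against gene
    intervals expanded by ``flank_bp`` on both sides. Transcripts on
    chromosomes absent from the annotation are removed as "unplaced".
    """
    by_chrom = annotation.genes_by_chrom(biotype=biotype)
    known_chroms = {g.chrom for g in annotation.genes} | set(annotation.chrom_lengths)
    kept: list[TranscriptModel] = []
    dropped: list[tuple[TranscriptModel, str]] = []
    for t in transcripts:
        if t.chrom not in known_chroms:
            warnings.warn(f"{t.transcript_id}: chromosome {t.chrom} not in annotation")
            dropped.append((t, "unplaced"))
            continue
        overlapping = False
        for g in by_chrom.get(t.chrom, []):
            if t.start < g.end + flank_bp and g.start - flank_bp < t.end:
                overlapping = True
                break
        if overlapping:
            dropped.append((t, "overlaps_gene_or_flank"))
        else:
            kept.append(t)
    return kept, dropped


def _reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def longest_orf(sequence: str, transcript_id: str = "") -> OrfResult:
    """Longest ATG..stop ORF over all six frames.

    Length is reported in amino acids excluding the stop codon; codons
    containing N never match start or stop. Ties across frames resolve to
    the first frame in the order +1,+2,+3,-1,-2,-3. Coordinates are in the
    forward transcript coordinate system.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    L = len(seq)
    best: tuple[int, str, int, int] | None = None  # (aa, frame, start, end)

    def scan(s: str, frame_label: str, minus: bool):
        nonlocal best
        offset = int(frame_label[1]) - 1
        open_start: int | None = None
        for i in range(offset, len(s) - 2, 3):
            codon = s[i : i + 3]
            if open_start is None:
                if codon == "ATG":
                    open_start = i
            elif codon in STOP_CODONS:
                aa = (i - open_start) // 3
                a, b = open_start, i + 3  # includes stop codon
                if minus:  # map back to forward coordinates
                    a, b = len(s) - b, len(s) - a
                if best is None or aa > best[0]:
                    best = (aa, frame_label, a, b)
                open_start = None

    scan(seq, "+1", False)
    scan(seq, "+2", False)
    scan(seq, "+3", False)
    rc = _reverse_complement(seq)
    scan(rc, "-1", True)
    scan(rc, "-2", True)
    scan(rc, "-3", True)
    if best is None:
        return OrfResult(transcript_id, 0, "+1", 0, 0)
    aa, frame, a, b = best
    return OrfResult(transcript_id, aa, frame, a, b)


def orf_reading_sequence(sequence: str, orf: OrfResult) -> str:
    """The ORF (ATG..stop inclusive) in its reading orientation."""
    sub = sequence.upper()[orf.orf_start : orf.orf_end]
    if orf.frame.startswith("-"):
        sub = _reverse_complement(sub)
    return sub


def filter_orf(
    transcripts: Sequence[TranscriptModel], max_orf_aa: int = 100
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Keep transcripts whose longest ORF is < max_orf_aa amino acids."""
    kept, dropped = [], []
    for t in transcripts:
        if t.sequence is None:
            raise ValueError(f"{t.transcript_id}: no sequence attached")
        if longest_orf(t.sequence, t.transcript_id).longest_orf_aa < max_orf_aa:
            kept.append(t)
        else:
            dropped.append(t)
    return kept, dropped


def coding_score(
    sequence: str,
    hexamer_model: Mapping[str, float] | None = None,
    transcript_id: str = "",
) -> CodingScore:
    """Mean hexamer log-likelihood ratio over the longest ORF.

    Hexamers are read in frame (step 3) inside the longest ORF; if no ORF
    exists the whole sequence is read in frame +1. A score > 0 labels the
    transcript coding.
    """
    if len(sequence) < 6:
        raise ValueError("sequence shorter than one hexamer")
    model = hexamer_model if hexamer_model is not None else hexamer_log_ratios()
    orf = longest_orf(sequence, transcript_id)
    window = orf_reading_sequence(sequence, orf) if orf.longest_orf_aa > 0 else sequence.upper()
    values = []
    for i in range(0, len(window) - 5, 3):
        hexamer = window[i : i + 6]
        if hexamer not in model:
            raise KeyError(f"hexamer {hexamer!r} missing from model")
        values.append(model[hexamer])
    if not values:
        raise ValueError("no scorable hexamer window")
    return CodingScore(transcript_id, sum(values) / len(values))


_aligner: Align.PairwiseAligner | None = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = 1
        a.mismatch_score = -2
        a.open_gap_score = -5
        a.extend_gap_score = -2
        _aligner = a
    return _aligner


def pairwise_identity(a: str, b: str) -> float:
    """Identity of the best local alignment over the shorter sequence length."""
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = _get_aligner()
    alignments = aligner.align(a, b)
    if len(alignments) == 0:
        return 0.0
    counts = alignments[0].counts()
    return counts.identities / min(len(a), len(b))


def filter_housekeeping(
    candidates: Sequence[TranscriptModel],
    hk_db: Mapping[str, str] | None = None,
    hits: Iterable[AlignmentHit] | None = None,
    e_value_max: float = 1e-5,
) -> tuple[list[TranscriptModel], list[tuple[TranscriptModel, str]]]:
    """Remove candidates with a housekeeping-RNA hit at E <= e_value_max.

    Either a housekeeping FASTA (searched with the built-in seed-and-extend
    aligner) or pre-computed tabular hits may be supplied.
    """
    from .conservation import SearchParams, local_align

    best_hit: dict[str, AlignmentHit] = {}
    if hits is not None:
        for h in hits:
            if h.e_value <= e_value_max:
                cur = best_hit.get(h.query_id)
                if cur is None or h.e_value < cur.e_value:
                    best_hit[h.query_id] = h
    if hk_db is not None:
        params = SearchParams(e_value_max=e_value_max, min_identity=0.0)
        for t in candidates:
            if t.sequence is None:
                raise ValueError(f"{t.transcript_id}: no sequence attached")
            if t.transcript_id in best_hit:
                continue
            for name, hk_seq in hk_db.items():
                found = local_align(t.sequence, hk_seq, params, t.transcript_id, name)
                if found:
                    best = min(found, key=lambda h: h.e_value)
                    cur = best_hit.get(t.transcript_id)
                    if cur is None or best.e_value < cur.e_value:
                        best_hit[t.transcript_id] = best
    kept, dropped = [], []
    for t in candidates:
        if t.transcript_id in best_hit:
            h = best_hit[t.transcript_id]
            dropped.append((t, f"housekeeping:{h.subject_id}:E={h.e_value:.3g}"))
        else:
            kept.append(t)
    return kept, dropped


def cluster_redundant(
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    identity: float = 0.95,
) -> tuple[list[Cluster], list[str]]:
    """Greedy incremental redundancy clustering.

    Sequences are visited longest-first (ties: ID ascending); each joins the
    first cluster whose representative it matches at >= identity (matching
    positions of the best local alignment divided by the shorter length),
    else founds a new cluster. Returns clusters plus representative IDs in
    input order.
    """
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    input_order = [tid for tid, _ in items]
    seqs = dict(items)
    for tid, s in items:
        if not s:
            raise ValueError(f"{tid}: empty sequence")
    order = sorted(input_order, key=lambda tid: (-len(seqs[tid]), tid))
    clusters: list[Cluster] = []
    for tid in order:
        placed = False
        for c in clusters:
            ident = pairwise_identity(seqs[tid], seqs[c.representative_id])
            if ident >= identity:
                c.member_ids.add(tid)
                c.identities[tid] = ident
                placed = True
                break
        if not placed:
            clusters.append(Cluster(tid, {tid}, {tid: 1.0}))
    rep_ids = {c.representative_id for c in clusters}
    representatives = [tid for tid in input_order if tid in rep_ids]
    return clusters, representatives


# ---------------------------------------------------------------------------
# Whole cascade


@dataclass
class PipelineResult:
    catalog: list[TranscriptModel]
    report: FilterReport
    clusters: list[Cluster]


def run_pipeline(
    assembly: Sequence[TranscriptModel],
    genome: Mapping[str, str],
    annotation: GenomeAnnotation,
    hk_db: Mapping[str, str] | None = None,
    hk_hits: Iterable[AlignmentHit] | None = None,
    external_coding_ids: set[str] | None = None,
    min_length: int = 200,
    orf_max: int = 100,
    flank_bp: int = 500,
    hk_evalue: float = 1e-5,
    cluster_identity: float = 0.95,
    hexamer_model: Mapping[str, float] | None = None,
) -> PipelineResult:
    """Run the full identification cascade and return the lincRNA catalog.

    Stage order: length >= min_length -> intergenic/flank -> coding-potential
    score (unioned with any external classifier calls) -> ORF < orf_max ->
    housekeeping similarity -> redundancy clustering. Deterministic given
    identical inputs.
    """
    report = FilterReport(
        params={
            "min_length": min_length,
            "orf_max": orf_max,
            "flank_bp": flank_bp,
            "hk_evalue": hk_evalue,
            "cluster_identity": cluster_identity,
        }
    )
    current = list(assembly)
    report.record("input", {t.transcript_id for t in current}, set())

    kept, dropped = filter_length(current, min_length)
    report.record(
        "length",
        {t.transcript_id for t in kept},
        {(t.transcript_id, f"short:{t.length}bp") for t in dropped},
    )
    current = kept

    kept, dropped_r = classify_intergenic(current, annotation, flank_bp)
    report.record(
        "intergenic",
        {t.transcript_id for t in kept},
        {(t.transcript_id, reason) for t, reason in dropped_r},
    )
    current = kept

    # sequences are needed from here on
    for t in current:
        if t.sequence is None:
            t.sequence = extract_sequence(genome, t)

    coding_ids = set(external_coding_ids or ())
    kept, dropped = [], []
    for t in current:
        cs = coding_score(t.sequence, hexamer_model, t.transcript_id)
        if cs.label == "coding" or t.transcript_id in coding_ids:
            dropped.append((t, f"coding_score:{cs.score:.3f}"))
        else:
            kept.append(t)
    report.record(
        "coding_potential",
        {t.transcript_id for t in kept},
        {(t.transcript_id, reason) for t, reason in dropped},
    )
    current = kept

    kept, dropped_t = filter_orf(current, orf_max)
    report.record(
        "orf",
        {t.transcript_id for t in kept},
        {
            (t.transcript_id, f"long_orf:{longest_orf(t.sequence).longest_orf_aa}aa")
            for t in dropped_t
        },
    )
    current = kept

    kept, dropped_r = filter_housekeeping(current, hk_db, hk_hits, hk_evalue)
    report.record(
        "housekeeping",
        {t.transcript_id for t in kept},
        {(t.transcript_id, reason) for t, reason in dropped_r},
    )
    current = kept

    clusters, rep_ids = cluster_redundant(
        [(t.transcript_id, t.sequence) for t in current], cluster_identity
    )
    rep_set = set(rep_ids)
    removed = set()
    for c in clusters:
        for m in sorted(c.member_ids - {c.representative_id}):
            removed.add((m, f"redundant_with:{c.representative_id}"))
    report.record("cluster", rep_set, removed)

    catalog = [t for t in current if t.transcript_id in rep_set]
    report.validate()
    logger.info("pipeline counts: %s", report.counts())
    return PipelineResult(catalog=catalog, report=report, clusters=clusters)
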