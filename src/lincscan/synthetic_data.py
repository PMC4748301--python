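"""Synthetic study generator with planted ground truth.

Builds a toy genome, gene annotation, transcript assembly, housekeeping-RNA
database, subject genomes, and tissue/development expression matrices in
which every downstream result is known by construction: planted lincRNAs
that pass the whole identification cascade, one decoy class per filter,
cross-genome copies for the conservation search, tissue- and stage-specific
expression, on/off settlement contrasts, and co-expression modules whose
eigen-profiles track development-time rank.

The generator self-checks each planted object against the same filter
oracles the pipeline uses (ORF length, coding score, housekeeping hit,
duplicate identity, tau) and re-draws until the check passes, so recovery
tests are exact rather than probabilistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import pipeline_filters as pf
from .expression_profiles import tau
from .hexamer import interior_codon_distribution
from .io_formats import (
    ExpressionMatrix,
    Gene,
    GenomeAnnotation,
    SampleMeta,
    TranscriptModel,
    write_annotation_gtf,
    write_expression_table,
    write_fasta,
    write_gtf,
    write_sample_metadata,
)

TISSUE_PANEL = (
    "gill",
    "hemolymph",
    "digestive_gland",
    "labial_palp",
    "female_gonad",
    "male_gonad",
    "mantle_inner",
    "mantle_edge",
    "adductor_muscle",
)

STAGE_NAMES = ("embryo", "trochophore", "d_shaped", "umbo", "pediveliger", "spat")

BASES = np.array(list("ACGT"))
NONCODING_P = np.array([0.30, 0.20, 0.20, 0.30])
STOPS = ("TAA", "TAG", "TGA")
SUBJECT_SPECIES = ("lottia", "aplysia", "biomphalaria", "pinctada")


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-design knobs; the defaults define the default simulated scene."""

    seed: int = 0
    n_coding_genes: int = 200
    n_linc_loci: int = 50
    n_decoys_per_class: int = 10
    chrom_length: int = 4_000_000
    flank_bp: int = 500
    tissue_panel: tuple[str, ...] = TISSUE_PANEL
    n_timepoints: int = 34
    n_stages: int = 6
    module_spec: tuple[tuple[int, int], ...] = ((50, 1), (50, -1), (50, 1))
    noise_sd: float = 0.3
    hub_noise_sd: float = 0.08
    mutation_rate: float = 0.02
    subject_genome_length: int = 60_000
    n_conserved_all: int = 10
    n_conserved_one: int = 10
    n_housekeeping_entries: int = 20
    n_tissue_specific: int = 15
    n_stage_specific: int = 10
    n_settlement_each: int = 5
    lincs_per_module: int = 5
    two_exon_fraction: float = 0.04
    off_fpkm: float = 1.0
    hi_fpkm: float = 5.0

    def __post_init__(self) -> None:
        if self.n_timepoints < 4:
            raise SimulationError("n_timepoints must be >= 4")
        if self.n_stages < 2 or self.n_stages > len(STAGE_NAMES):
            raise SimulationError(f"n_stages must be in 2..{len(STAGE_NAMES)}")


@dataclass
class TruthTable:
    """Planted ground truth for recovery tests."""

    planted_linc_ids: list[str] = field(default_factory=list)
    coding_ids: list[str] = field(default_factory=list)
    gene_of_transcript: dict[str, str] = field(default_factory=dict)
    short_decoy_ids: list[str] = field(default_factory=list)
    inside_gene_decoy_ids: list[str] = field(default_factory=list)
    flank_decoy_ids: list[str] = field(default_factory=list)
    long_orf_decoy_ids: list[str] = field(default_factory=list)
    housekeeping_like_ids: list[str] = field(default_factory=list)
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    tissue_specific_map: dict[str, str] = field(default_factory=dict)
    stage_specific_map: dict[str, str] = field(default_factory=dict)
    settlement_on_a: set[str] = field(default_factory=set)
    settlement_on_b: set[str] = field(default_factory=set)
    module_assignment: dict[str, str] = field(default_factory=dict)
    module_sign: dict[str, int] = field(default_factory=dict)
    hub_ids: dict[str, str] = field(default_factory=dict)
    linked_linc_ids: dict[str, str] = field(default_factory=dict)
    conserved_all_ids: set[str] = field(default_factory=set)
    conserved_map: dict[str, set[str]] = field(default_factory=dict)
    term_map: dict[str, set[str]] = field(default_factory=dict)
    enriched_terms: dict[str, str] = field(default_factory=dict)

    def decoy_ids(self) -> set[str]:
        return (
            set(self.short_decoy_ids)
            | set(self.inside_gene_decoy_ids)
            | set(self.flank_decoy_ids)
            | set(self.long_orf_decoy_ids)
            | set(self.housekeeping_like_ids)
            | {d for d, _ in self.duplicate_pairs}
        )

    def write_tsv(self, path) -> None:
        rows = []
        classes = [
            ("linc", self.planted_linc_ids),
            ("coding", self.coding_ids),
            ("decoy_short", self.short_decoy_ids),
            ("decoy_inside_gene", self.inside_gene_decoy_ids),
            ("decoy_flank", self.flank_decoy_ids),
            ("decoy_long_orf", self.long_orf_decoy_ids),
            ("decoy_housekeeping_like", self.housekeeping_like_ids),
        ]
        for cls, ids in classes:
            for tid in ids:
                rows.append({"feature_id": tid, "class": cls, "detail": ""})
        for dup, parent in self.duplicate_pairs:
            rows.append({"feature_id": dup, "class": "decoy_duplicate", "detail": parent})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedScene:
    config: SimulationConfig
    genome: dict[str, str]
    annotation: GenomeAnnotation
    assembly: list[TranscriptModel]
    housekeeping_db: dict[str, str]
    subject_genomes: dict[str, dict[str, str]]
    truth: TruthTable

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_annotation_gtf(self.annotation, outdir / "annotation.gtf")
        write_gtf(self.assembly, outdir / "assembly.gtf")
        write_fasta(self.housekeeping_db, outdir / "housekeeping.fa")
        for sp, genome in self.subject_genomes.items():
            write_fasta(genome, outdir / f"subject_{sp}.fa")
        self.truth.write_tsv(outdir / "truth.tsv")
        with open(outdir / "term_map.tsv", "w") as fh:
            for gene in sorted(self.truth.term_map):
                for term in sorted(self.truth.term_map[gene]):
                    fh.write(f"{gene}\t{term}\n")
        def _plain(obj):
            if isinstance(obj, tuple):
                return [_plain(x) for x in obj]
            return obj

        cfg = {k: _plain(v) for k, v in asdict(self.config).items()}
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# sequence-level helpers


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length, p=NONCODING_P))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """i.i.d. substitutions (no indels) at the given per-base rate."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _coding_orf(rng: np.random.Generator, n_aa: int) -> str:
    codons, probs = interior_codon_distribution()
    body = "".join(rng.choice(codons, size=n_aa - 1, p=probs))
    return "ATG" + body + STOPS[rng.integers(3)]


def _noncoding_orf(rng: np.random.Generator, n_aa: int) -> str:
    """An ORF whose interior codons follow the noncoding base composition."""
    body = []
    while len(body) < n_aa - 1:
        codon = _random_seq(rng, 3)
        if codon not in STOPS:
            body.append(codon)
    return "ATG" + "".join(body) + STOPS[rng.integers(3)]


def _draw_linc_sequence(
    rng: np.random.Generator,
    length: int,
    hk_db: Mapping[str, str],
    max_orf_aa: int = 100,
    max_tries: int = 200,
) -> str:
    """A noncoding sequence that passes ORF, coding-score and housekeeping
    filters; re-drawn until the self-check passes."""
    for _ in range(max_tries):
        seq = _random_seq(rng, length)
        if _passes_noncoding_checks(seq, hk_db, max_orf_aa):
            return seq
    raise SimulationError("could not draw a lincRNA sequence passing self-checks")


def _passes_noncoding_checks(seq: str, hk_db: Mapping[str, str], max_orf_aa: int) -> bool:
    if pf.longest_orf(seq).longest_orf_aa >= max_orf_aa:
        return False
    if pf.coding_score(seq).score > 0:
        return False
    return not _has_hk_hit(seq, hk_db)


def _has_hk_hit(seq: str, hk_db: Mapping[str, str]) -> bool:
    from .conservation import SearchParams, local_align

    params = SearchParams(min_identity=0.0)
    return any(local_align(seq, hk_seq, params) for hk_seq in hk_db.values())


# ---------------------------------------------------------------------------
# genome + assembly


def simulate_genome(config: SimulationConfig) -> SimulatedScene:
    """Generate genome, annotation, assembly, housekeeping DB, subject
    genomes and the truth table for one seed."""
    rng = np.random.default_rng(config.seed)
    truth = TruthTable()
    chrom = "chr1"

    # housekeeping DB: first entries long enough to seed look-alike decoys
    hk_db: dict[str, str] = {}
    for i in range(config.n_housekeeping_entries):
        length = int(rng.integers(250, 600)) if i < max(10, config.n_decoys_per_class) else int(
            rng.integers(80, 1500)
        )
        hk_db[f"HK_{i:03d}"] = _random_seq(rng, length)

    # --- draw locus payloads -------------------------------------------------
    loci: list[dict] = []  # kind, seq/exonspec, extras

    for i in range(config.n_coding_genes):
        n_aa = int(rng.integers(150, 300))
        utr5 = _random_seq(rng, int(rng.integers(30, 80)))
        utr3 = _random_seq(rng, int(rng.integers(30, 80)))
        mrna = utr5 + _coding_orf(rng, n_aa) + utr3
        loci.append({"kind": "coding", "seq": mrna, "strand": "+" if rng.random() < 0.5 else "-"})

    n_two_exon = int(round(config.two_exon_fraction * config.n_linc_loci))
    linc_seqs: list[str] = []
    for i in range(config.n_linc_loci):
        length = int(rng.integers(250, 800))
        seq = _draw_linc_sequence(rng, length, hk_db)
        linc_seqs.append(seq)
        loci.append({"kind": "linc", "seq": seq, "two_exon": i < n_two_exon})

    for _ in range(config.n_decoys_per_class):
        loci.append({"kind": "decoy_short", "seq": _random_seq(rng, int(rng.integers(60, 200)))})

    for _ in range(config.n_decoys_per_class):
        for _try in range(200):
            n_aa = int(rng.integers(110, 150))
            seq = (
                _random_seq(rng, int(rng.integers(30, 60)))
                + _noncoding_orf(rng, n_aa)
                + _random_seq(rng, int(rng.integers(30, 60)))
            )
            if (
                pf.longest_orf(seq).longest_orf_aa >= 100
                and pf.coding_score(seq).score <= 0
                and not _has_hk_hit(seq, hk_db)
            ):
                break
        else:
            raise SimulationError("could not draw a long-ORF decoy")
        loci.append({"kind": "decoy_long_orf", "seq": seq})

    n_dups = min(config.n_decoys_per_class, config.n_linc_loci)
    for i in range(n_dups):
        parent = linc_seqs[i]
        for _try in range(200):
            dup = _mutate(rng, parent[: int(0.9 * len(parent))], config.mutation_rate)
            if (
                len(dup) >= 200
                and _passes_noncoding_checks(dup, hk_db, 100)
                and pf.pairwise_identity(dup, parent) >= 0.95
            ):
                break
        else:
            raise SimulationError("could not draw a near-duplicate decoy")
        loci.append({"kind": "decoy_duplicate", "seq": dup, "parent_index": i})

    hk_names = sorted(hk_db)
    for i in range(config.n_decoys_per_class):
        entry = hk_db[hk_names[i % len(hk_names)]]
        for _try in range(200):
            look = _mutate(rng, entry[: min(len(entry), 600)], config.mutation_rate)
            if (
                len(look) >= 200
                and pf.longest_orf(look).longest_orf_aa < 100
                and pf.coding_score(look).score <= 0
                and _has_hk_hit(look, hk_db)
            ):
                break
        else:
            raise SimulationError("could not draw a housekeeping look-alike")
        loci.append({"kind": "decoy_hk_like", "seq": look})

    # --- place loci on the chromosome ---------------------------------------
    order = rng.permutation(len(loci))
    intron_len = 200
    cursor = int(rng.integers(1_000, 3_000))
    placements: list[tuple[int, dict]] = []
    for idx in order:
        locus = loci[idx]
        footprint = len(locus["seq"]) + (intron_len if locus.get("two_exon") else 0)
        placements.append((cursor, locus))
        locus["start"] = cursor
        # mostly tight gene neighborhoods with occasional long deserts, so
        # nearest-neighbor distances straddle the 10 kb window
        if rng.random() < 0.8:
            gap = int(rng.integers(100, 6_000))
        else:
            gap = int(rng.integers(12_000, 28_000))
        cursor += footprint + 2 * config.flank_bp + gap
    if cursor > config.chrom_length:
        raise SimulationError(
            f"infeasible packing: loci + flanks need {cursor} bp > chrom_length "
            f"{config.chrom_length}"
        )

    genome_arr = np.array(list(_random_seq(rng, config.chrom_length)))
    tx_counter = 0
    genes: list[Gene] = []
    assembly: list[TranscriptModel] = []
    gene_counter = 0
    dup_parent: dict[str, int] = {}

    def next_tid() -> str:
        nonlocal tx_counter
        tx_counter += 1
        return f"TCONS_{tx_counter:08d}"

    for start, locus in placements:
        seq = locus["seq"]
        kind = locus["kind"]
        if locus.get("two_exon"):
            half = len(seq) // 2
            genome_arr[start : start + half] = list(seq[:half])
            genome_arr[start + half + intron_len : start + len(seq) + intron_len] = list(
                seq[half:]
            )
            exons = [(start, start + half), (start + half + intron_len, start + len(seq) + intron_len)]
        else:
            genome_arr[start : start + len(seq)] = list(seq)
            exons = [(start, start + len(seq))]
        tid = next_tid()
        locus["tid"] = tid
        if kind == "coding":
            gene_counter += 1
            gid = f"G{gene_counter:04d}"
            genes.append(Gene(gid, chrom, locus["strand"], start, start + len(seq)))
            assembly.append(TranscriptModel(tid, chrom, locus["strand"], exons))
            truth.coding_ids.append(gid)
            truth.gene_of_transcript[tid] = gid
            locus["gene_id"] = gid
        else:
            strand = "+" if locus.get("two_exon") else "."
            assembly.append(TranscriptModel(tid, chrom, strand, exons))
            if kind == "linc":
                truth.planted_linc_ids.append(tid)
            elif kind == "decoy_short":
                truth.short_decoy_ids.append(tid)
            elif kind == "decoy_long_orf":
                truth.long_orf_decoy_ids.append(tid)
            elif kind == "decoy_duplicate":
                dup_parent[tid] = locus["parent_index"]
            elif kind == "decoy_hk_like":
                truth.housekeeping_like_ids.append(tid)

    # duplicate parent_index refers to draw order of linc_seqs; loci preserves it
    linc_id_by_draw = {
        i: locus["tid"]
        for i, locus in enumerate(l for l in loci if l["kind"] == "linc")
    }
    for dup_tid, parent_i in sorted(dup_parent.items()):
        truth.duplicate_pairs.append((dup_tid, linc_id_by_draw[parent_i]))

    # flank + inside-gene decoys (placed relative to existing genes)
    coding_loci = [l for l in loci if l["kind"] == "coding"]
    if coding_loci:
        for i in range(config.n_decoys_per_class):
            host = coding_loci[int(rng.integers(len(coding_loci)))]
            length = int(rng.integers(200, 400))
            start = host["start"] + len(host["seq"]) + 50  # 50 bp into the flank
            tid = next_tid()
            assembly.append(TranscriptModel(tid, chrom, ".", [(start, start + length)]))
            truth.flank_decoy_ids.append(tid)
        for i in range(config.n_decoys_per_class):
            host = coding_loci[int(rng.integers(len(coding_loci)))]
            length = min(int(rng.integers(200, 300)), len(host["seq"]) - 60)
            start = host["start"] + 30
            tid = next_tid()
            assembly.append(TranscriptModel(tid, chrom, ".", [(start, start + length)]))
            truth.inside_gene_decoy_ids.append(tid)

    assembly.sort(key=lambda t: t.transcript_id)
    genome = {chrom: "".join(genome_arr)}
    annotation = GenomeAnnotation(genes=genes, chrom_lengths={chrom: config.chrom_length})

    # --- subject genomes ------------------------------------------------------
    subject_genomes: dict[str, dict[str, str]] = {}
    planted = truth.planted_linc_ids
    conserved_all = set(planted[: config.n_conserved_all])
    conserved_one = planted[
        config.n_conserved_all : config.n_conserved_all + config.n_conserved_one
    ]
    truth.conserved_all_ids = conserved_all
    linc_seq_by_id = {
        t.transcript_id: "".join(genome[chrom][s:e] for s, e in t.exons)
        for t in assembly
        if t.transcript_id in set(planted)
    }
    for si, species in enumerate(SUBJECT_SPECIES):
        to_plant = sorted(conserved_all) + [
            lid for j, lid in enumerate(conserved_one) if j % len(SUBJECT_SPECIES) == si
        ]
        truth.conserved_map[species] = set(to_plant)
        pos = int(rng.integers(500, 2_000))
        background = _random_seq(
            rng,
            config.subject_genome_length
            + sum(len(linc_seq_by_id[l]) for l in to_plant),
        )
        out = list(background)
        for lid in to_plant:
            copy = _mutate(rng, linc_seq_by_id[lid], config.mutation_rate)
            if rng.random() < 0.5:
                copy = copy.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            if pos + len(copy) > len(out):
                raise SimulationError("subject genome too short for planted copies")
            out[pos : pos + len(copy)] = list(copy)
            pos += len(copy) + int(rng.integers(1_000, 3_000))
        subject_genomes[species] = {f"{species}_scaffold1": "".join(out)}

    _assign_roles(config, truth, rng)
    _build_term_map(config, truth, rng)
    return SimulatedScene(
        config=config,
        genome=genome,
        annotation=annotation,
        assembly=assembly,
        housekeeping_db=hk_db,
        subject_genomes=subject_genomes,
        truth=truth,
    )


def _assign_roles(config: SimulationConfig, truth: TruthTable, rng: np.random.Generator):
    """Partition planted lincRNAs over expression roles and set up modules."""
    lincs = list(truth.planted_linc_ids)
    pool = lincs.copy()

    def take(n: int) -> list[str]:
        taken, rest = pool[:n], pool[n:]
        pool[:] = rest
        return taken

    tissues = list(config.tissue_panel)
    for lid in take(config.n_tissue_specific):
        # male gonad dominates tissue-specific expression in this system
        if "male_gonad" in tissues and rng.random() < 0.35:
            truth.tissue_specific_map[lid] = "male_gonad"
        else:
            truth.tissue_specific_map[lid] = tissues[int(rng.integers(len(tissues)))]
    stages = list(STAGE_NAMES[: config.n_stages])
    for lid in take(config.n_stage_specific):
        # terminal sessile stage dominates stage-specific expression
        if rng.random() < 0.7:
            truth.stage_specific_map[lid] = stages[-1]
        else:
            truth.stage_specific_map[lid] = stages[int(rng.integers(len(stages) - 1))]
    truth.settlement_on_a = set(take(config.n_settlement_each))
    truth.settlement_on_b = set(take(config.n_settlement_each))
    # single-stage lincRNAs of the two contrasted stages are, by definition,
    # also on/off across the settlement boundary; the expected contrast sets
    # include them
    eyed, spat = stages[-2], stages[-1]
    for lid, st in truth.stage_specific_map.items():
        if st == eyed:
            truth.settlement_on_a.add(lid)
        elif st == spat:
            truth.settlement_on_b.add(lid)

    coding_pool = list(truth.coding_ids)
    for m, (size, sign) in enumerate(config.module_spec):
        label = f"M{m + 1}"
        n_lincs = min(config.lincs_per_module, len(pool), size)
        member_lincs = take(n_lincs)
        n_coding = size - n_lincs
        if n_coding > len(coding_pool):
            raise SimulationError("module sizes exceed available coding genes")
        member_coding = coding_pool[:n_coding]
        coding_pool = coding_pool[n_coding:]
        for fid in member_coding + member_lincs:
            truth.module_assignment[fid] = label
        truth.module_sign[label] = sign
        if member_coding:
            truth.hub_ids[label] = member_coding[0]
        if member_lincs:
            truth.linked_linc_ids[label] = member_lincs[0]
    for fid in coding_pool + pool:
        truth.module_assignment[fid] = "background"


def _build_term_map(config: SimulationConfig, truth: TruthTable, rng: np.random.Generator):
    background_terms = [f"GO:09{i:05d}" for i in range(30)]
    for gid in truth.coding_ids:
        n = int(rng.integers(2, 5))
        for t in rng.choice(background_terms, size=n, replace=False):
            truth.term_map.setdefault(gid, set()).add(str(t))
    for m, _ in enumerate(config.module_spec):
        label = f"M{m + 1}"
        term = f"GO:08{m:05d}"
        truth.enriched_terms[label] = term
        members = [
            g for g in truth.coding_ids if truth.module_assignment.get(g) == label
        ]
        for g in members:
            if rng.random() < 0.85:
                truth.term_map.setdefault(g, set()).add(term)
        for g in truth.coding_ids:
            if truth.module_assignment.get(g) != label and rng.random() < 0.02:
                truth.term_map.setdefault(g, set()).add(term)


# ---------------------------------------------------------------------------
# expression


def _stage_partition(n_timepoints: int, n_stages: int) -> list[str]:
    chunks = np.array_split(np.arange(n_timepoints), n_stages)
    labels = []
    for stage, chunk in zip(STAGE_NAMES[:n_stages], chunks):
        labels.extend([stage] * len(chunk))
    return labels


def module_eigen_profiles(n_timepoints: int, n_modules: int) -> list[np.ndarray]:
    """Planted module eigen-profiles over development-time rank.

    Each profile is a strictly monotone sigmoid (plus a small linear term)
    whose transition point differs per module, standardized to mean 0 / sd 1.
    Strict monotonicity makes the Spearman correlation with time rank
    exactly +-1, while the staggered transitions keep cross-module Pearson
    correlations low enough that modules stay separable in the network.
    """
    r = np.arange(1, n_timepoints + 1, dtype=float)
    centers = np.linspace(0.12, 0.88, n_modules) * (n_timepoints + 1)
    width = n_timepoints / 18.0
    profiles = []
    for c in centers:
        p = 1.0 / (1.0 + np.exp(-(r - c) / width)) + 0.06 * (r - 1) / (n_timepoints - 1)
        profiles.append((p - p.mean()) / p.std())
    return profiles


def development_samples(config: SimulationConfig) -> list[SampleMeta]:
    days = np.round(np.linspace(0.25, 23.0, config.n_timepoints), 2)
    stages = _stage_partition(config.n_timepoints, config.n_stages)
    return [
        SampleMeta(
            sample_id=f"T{i + 1:02d}",
            time_days=float(days[i]),
            time_rank=i + 1,
            stage=stages[i],
        )
        for i in range(config.n_timepoints)
    ]


def simulate_expression(
    truth: TruthTable, config: SimulationConfig
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Tissue and development FPKM matrices matching the planted roles.

    Tissue-specific lincRNAs get high log-normal FPKM in their tissue and
    < 0.5 elsewhere (tau > 0.95 guaranteed by a generation-time check);
    module members follow a monotone eigen-profile in development-time rank
    plus Gaussian noise on the log2 scale; stage-specific and settlement
    lincRNAs are on/off by stage.
    """
    rng = np.random.default_rng(config.seed + 1)
    features = list(truth.coding_ids) + list(truth.planted_linc_ids)
    linc_set = set(truth.planted_linc_ids)
    tissues = list(config.tissue_panel)

    # ---- tissue matrix
    tissue_rows = {}
    for fid in features:
        if fid in truth.tissue_specific_map:
            for _try in range(100):
                row = rng.uniform(0.0, 0.4, size=len(tissues))
                on = tissues.index(truth.tissue_specific_map[fid])
                row[on] = 2.0 ** rng.normal(5.0, 0.3) - 1.0
                if tau(row) > 0.95:
                    break
            else:
                raise SimulationError("could not plant a tissue-specific profile")
        else:
            # per-feature baseline spread makes the lincRNA and mRNA
            # expression-level distributions overlap rather than separate
            # cleanly; tau is scale-invariant, so the broad check still holds
            base = max(0.5, (2.0 if fid in linc_set else 5.0) + rng.normal(0.0, 0.8))
            for _try in range(100):
                row = np.maximum(
                    2.0 ** (base + rng.normal(0.0, 0.15, size=len(tissues))) - 1.0, 0.0
                )
                if tau(row) < 0.5:
                    break
            else:
                raise SimulationError("could not plant a broad profile")
        tissue_rows[fid] = row
    tissue_samples = [SampleMeta(sample_id=t, tissue=t) for t in tissues]
    tissue_matrix = ExpressionMatrix(
        pd.DataFrame.from_dict(tissue_rows, orient="index", columns=tissues).loc[features],
        tissue_samples,
        feature_kind={f: ("lincRNA" if f in linc_set else "mRNA") for f in features},
    )

    # ---- development matrix
    samples = development_samples(config)
    n = config.n_timepoints
    profiles = module_eigen_profiles(n, len(config.module_spec))
    stage_of = [m.stage for m in samples]
    dev_rows = {}
    hubs = set(truth.hub_ids.values())
    linked = set(truth.linked_linc_ids.values())
    for fid in features:
        label = truth.module_assignment.get(fid, "background")
        if fid in truth.stage_specific_map:
            on_stage = truth.stage_specific_map[fid]
            row = rng.uniform(0.0, 0.8, size=n)
            on_idx = [i for i, s in enumerate(stage_of) if s == on_stage]
            row[on_idx] = 2.0 ** rng.normal(5.0, 0.3, size=len(on_idx)) - 1.0
        elif fid in truth.settlement_on_a or fid in truth.settlement_on_b:
            if fid in truth.settlement_on_a:  # on before settlement, off after
                on_stages = set(STAGE_NAMES[: config.n_stages][-3:-1])  # umbo+pediveliger
            else:  # on after settlement (and earliest stage), off in eyed larvae
                on_stages = {STAGE_NAMES[0], STAGE_NAMES[: config.n_stages][-1]}
            row = rng.uniform(0.0, 0.8, size=n)
            on_idx = [i for i, s in enumerate(stage_of) if s in on_stages]
            row[on_idx] = 2.0 ** rng.normal(5.0, 0.3, size=len(on_idx)) - 1.0
        elif label != "background":
            sign = truth.module_sign[label]
            e_profile = profiles[int(label[1:]) - 1]
            if fid in hubs:
                sd = config.hub_noise_sd
            elif fid in linked:
                sd = config.hub_noise_sd * 1.5
            elif fid in _co_candidates(truth, label):
                sd = config.hub_noise_sd * 1.25
            else:
                sd = config.noise_sd
            log2fpkm = 5.0 + 2.0 * sign * e_profile + rng.normal(0.0, sd, size=n)
            row = 2.0**log2fpkm - 1.0
        else:
            row = 2.0 ** (5.0 + rng.normal(0.0, 1.0, size=n)) - 1.0
        dev_rows[fid] = np.clip(row, 0.0, None)
    dev_matrix = ExpressionMatrix(
        pd.DataFrame.from_dict(
            dev_rows, orient="index", columns=[m.sample_id for m in samples]
        ).loc[features],
        samples,
        feature_kind={f: ("lincRNA" if f in linc_set else "mRNA") for f in features},
    )
    return tissue_matrix, dev_matrix


def _co_candidates(truth: TruthTable, label: str) -> set[str]:
    """Second and third coding members: near-hub noise so the module has a
    small low-noise core (the hub stays the best-connected node)."""
    members = [
        g for g in truth.coding_ids if truth.module_assignment.get(g) == label
    ]
    return set(members[1:3])
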