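"""Cross-genome homology search for lincRNAs.

A word-seeded, ungapped-extension local aligner (match +1 / mismatch -2,
X-drop termination) with Karlin-Altschul E-values, plus conservation
summaries over multiple subject genomes. Both strands of the subject are
searched, mirroring how nucleotide homology searches treat query strands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import AlignmentHit

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SearchParams:
    """Scoring and filtering parameters for the local search.

    lambda/K are the published ungapped Karlin-Altschul parameters for the
    +1/-2 scoring scheme; E = K * m * n * exp(-lambda * S).
    """

    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    x_drop: int = 20
    lam: float = 1.28
    k_const: float = 0.46
    e_value_max: float = 1e-5
    min_identity: float = 0.20

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.e_value_max <= 0:
            raise ValueError("e_value_max must be > 0")
        if not 0 <= self.min_identity <= 1:
            raise ValueError("min_identity outside [0,1]")

    def e_value(self, score: float, m: int, n: int) -> float:
        return self.k_const * m * n * math.exp(-self.lam * score)


@dataclass
class ConservationSummary:
    per_species_conserved: dict[str, set[str]]
    intersection_all: set[str]

    def counts(self) -> dict[str, int]:
        out = {sp: len(ids) for sp, ids in sorted(self.per_species_conserved.items())}
        out["all_species"] = len(self.intersection_all)
        return out


def _index_words(subject: str, w: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for j in range(len(subject) - w + 1):
        word = subject[j : j + w]
        if "N" in word:
            continue
        index.setdefault(word, []).append(j)
    return index


def _extend_seed(
    q: str, s: str, qi: int, si: int, w: int, params: SearchParams
) -> tuple[int, int, int, int, int]:
    """Ungapped X-drop extension of an exact seed; returns the best-scoring
    segment as (q_start, q_end, s_start, s_end, score)."""
    match, mismatch, xd = params.match, params.mismatch, params.x_drop
    # right extension from the end of the seed
    score = w * match
    best = score
    qr, sr = qi + w, si + w
    best_qr = qr
    while qr < len(q) and sr < len(s):
        score += match if q[qr] == s[sr] else mismatch
        qr += 1
        sr += 1
        if score > best:
            best, best_qr = score, qr
        elif best - score > xd:
            break
    # left extension from the start of the seed
    score = best
    best_ql = qi
    ql, sl = qi, si
    while ql > 0 and sl > 0:
        ql -= 1
        sl -= 1
        score += match if q[ql] == s[sl] else mismatch
        if score > best:
            best, best_ql = score, ql
        elif best - score > xd:
            break
    d = si - qi
    return best_ql, best_qr, best_ql + d, best_qr + d, best


def _align_one_strand(
    query: str,
    subject: str,
    params: SearchParams,
    index: dict[str, list[int]],
) -> list[tuple[int, int, int, int, int]]:
    w = params.word_size
    covered: dict[int, int] = {}  # diagonal -> query end already extended through
    segments: list[tuple[int, int, int, int, int]] = []
    for i in range(len(query) - w + 1):
        word = query[i : i + w]
        if "N" in word:
            continue
        for j in index.get(word, ()):
            diag = j - i
            if covered.get(diag, -1) >= i + w:
                continue
            seg = _extend_seed(query, subject, i, j, w, params)
            covered[diag] = seg[1]
            segments.append(seg)
    # keep the best segment per diagonal among overlapping ones
    segments.sort(key=lambda t: (-t[4], t[0]))
    kept: list[tuple[int, int, int, int, int]] = []
    occupied: dict[int, list[tuple[int, int]]] = {}
    for seg in segments:
        ql, qr, sl, sr, score = seg
        diag = sl - ql
        spans = occupied.setdefault(diag, [])
        if any(ql < b and a < qr for a, b in spans):
            continue
        spans.append((ql, qr))
        kept.append(seg)
    return kept


def local_align(
    query: str,
    subject: str,
    params: SearchParams | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> list[AlignmentHit]:
    """Seed-and-extend ungapped local alignment of query against subject.

    Exact word_size-mer seeds are located via a subject index and extended
    ungapped in both directions with X-drop termination. Hits are scored
    S = matches - 2*mismatches, assigned E = K*m*n*exp(-lambda*S), and kept
    when E <= e_value_max and identity >= min_identity. Both subject strands
    are searched; hit coordinates are on the forward subject strand.
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    params = params or SearchParams()
    query = query.upper()
    subject = subject.upper()
    m, n = len(query), len(subject)
    hits: list[AlignmentHit] = []
    for strand, subj in (("+", subject), ("-", subject.translate(_COMPLEMENT)[::-1])):
        index = _index_words(subj, params.word_size)
        for ql, qr, sl, sr, score in _align_one_strand(query, subj, params, index):
            length = qr - ql
            matches = sum(1 for a, b in zip(query[ql:qr], subj[sl:sr]) if a == b)
            identity = matches / length
            e = params.e_value(score, m, n)
            if e > params.e_value_max or identity < params.min_identity:
                continue
            if strand == "-":
                sl, sr = n - sr, n - sl
            hits.append(
                AlignmentHit(
                    query_id=query_id,
                    subject_id=subject_id,
                    percent_identity=identity,
                    align_length=length,
                    q_start=ql,
                    q_end=qr,
                    s_start=sl,
                    s_end=sr,
                    score=float(score),
                    e_value=e,
                )
            )
    hits.sort(key=lambda h: (h.e_value, h.q_start, h.s_start))
    return hits


def search_genome(
    query: str,
    genome: Mapping[str, str],
    params: SearchParams | None = None,
    query_id: str = "query",
) -> list[AlignmentHit]:
    """local_align of one query against every chromosome of a genome."""
    hits: list[AlignmentHit] = []
    for chrom in sorted(genome):
        hits.extend(local_align(query, genome[chrom], params, query_id, chrom))
    hits.sort(key=lambda h: (h.e_value, h.subject_id, h.q_start))
    return hits


def conservation_summary(
    lincs: Mapping[str, str],
    subject_genomes: Mapping[str, Mapping[str, str]],
    params: SearchParams | None = None,
    imported_hits: Mapping[str, Iterable[AlignmentHit]] | None = None,
) -> ConservationSummary:
    """Which lincRNAs have >= 1 surviving hit in each subject species.

    ``imported_hits`` (species -> tabular hits) may replace the built-in
    search for any species; imported hits are filtered with the same
    E-value and identity thresholds.
    """
    params = params or SearchParams()
    per_species: dict[str, set[str]] = {}
    imported = dict(imported_hits or {})
    for species in sorted(set(subject_genomes) | set(imported)):
        conserved: set[str] = set()
        if species in imported:
            for h in imported[species]:
                if h.e_value <= params.e_value_max and h.percent_identity >= params.min_identity:
                    conserved.add(h.query_id)
        else:
            genome = subject_genomes[species]
            for linc_id in sorted(lincs):
                if search_genome(lincs[linc_id], genome, params, linc_id):
                    conserved.add(linc_id)
        per_species[species] = conserved
    if per_species:
        intersection = set.intersection(*per_species.values())
    else:
        intersection = set()
    return ConservationSummary(per_species_conserved=per_species, intersection_all=intersection)
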