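"""Expression profiling of the lincRNA catalog.

Expressed sets (FPKM >= 1), the tissue-specificity index tau, stage-specific
calls, settlement-style on/off contrasts between two stages, lincRNA-vs-mRNA
expression-level comparison (KDE + two-sample Kolmogorov-Smirnov), and
nearest protein-coding-neighbor distances.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import ExpressionMatrix, GenomeAnnotation, TranscriptModel


@dataclass
class SpecificityResult:
    feature_id: str
    tau: float
    argmax_tissue: str
    expressed_anywhere: bool


@dataclass
class StageCall:
    feature_id: str
    stages_expressed: set[str]

    @property
    def specific_stage(self) -> str | None:
        if len(self.stages_expressed) == 1:
            return next(iter(self.stages_expressed))
        return None


@dataclass
class NeighborResult:
    linc_id: str
    nearest_gene_id: str
    distance_bp: int

    @property
    def within_10kb(self) -> bool:
        return self.distance_bp < 10_000


def expressed_set(matrix: ExpressionMatrix, min_fpkm: float = 1.0) -> set[str]:
    """Features whose maximum FPKM over samples is >= min_fpkm."""
    mask = matrix.values.max(axis=1) >= min_fpkm
    return set(matrix.values.index[mask])


def tau(expression_vector: Sequence[float]) -> float:
    """Tissue-specificity index: sum_i (1 - x_i/x_max) / (N - 1).

    0 for perfectly uniform expression, 1 for single-tissue expression.
    Requires >= 2 tissues and a positive maximum.
    """
    x = np.asarray(expression_vector, dtype=float)
    if x.size < 2:
        raise ValueError("tau requires >= 2 tissues")
    if (x < 0).any():
        raise ValueError("negative expression values")
    x_max = x.max()
    if x_max == 0:
        raise ValueError("tau undefined for an all-zero vector")
    return float(np.sum(1.0 - x / x_max) / (x.size - 1))


def tissue_specific(
    matrix: ExpressionMatrix,
    tau_threshold: float = 0.95,
    min_fpkm: float = 1.0,
    scale: str = "raw",
) -> tuple[dict[str, SpecificityResult], Counter]:
    """Per-feature tau over per-tissue mean FPKM, plus per-tissue counts.

    Features are restricted to the expressed set. Multi-sample tissues are
    averaged before tau. ``scale`` is "raw" (default) or "log2p1".
    """
    tissues = matrix.sample_attr("tissue")
    if any(t is None for t in tissues):
        raise ValueError("all samples need tissue metadata")
    per_tissue = matrix.values.T.groupby(np.asarray(tissues)).mean().T
    if scale == "log2p1":
        per_tissue = np.log2(per_tissue + 1.0)
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")
    expressed = expressed_set(matrix, min_fpkm)
    results: dict[str, SpecificityResult] = {}
    counts: Counter = Counter()
    for fid in matrix.feature_ids:
        if fid not in expressed:
            continue
        row = per_tissue.loc[fid]
        t = tau(row.to_numpy())
        top = row.idxmax()
        results[fid] = SpecificityResult(fid, t, top, True)
        if t > tau_threshold:
            counts[top] += 1
    return results, counts


def stage_specific(matrix: ExpressionMatrix, min_fpkm: float = 1.0) -> list[StageCall]:
    """Stage membership calls: expressed in a stage iff max FPKM there >= min_fpkm."""
    stages = matrix.sample_attr("stage")
    if any(s is None for s in stages):
        raise ValueError("all samples need stage metadata")
    stage_cols: dict[str, list[str]] = {}
    for sid, st in zip(matrix.sample_ids, stages):
        stage_cols.setdefault(st, []).append(sid)
    calls = []
    for fid in matrix.feature_ids:
        row = matrix.values.loc[fid]
        expressed_in = {
            st for st, cols in stage_cols.items() if row[cols].max() >= min_fpkm
        }
        calls.append(StageCall(fid, expressed_in))
    return calls


def settlement_contrast(
    matrix: ExpressionMatrix,
    stage_a: str,
    stage_b: str,
    hi_fpkm: float = 5.0,
    off_fpkm: float = 1.0,
) -> tuple[set[str], set[str]]:
    """On/off contrast between two stages.

    First set: max FPKM >= hi_fpkm in stage_a samples and < off_fpkm in
    stage_b samples; the second set is the symmetric complement.
    """
    stages = matrix.sample_attr("stage")
    cols_a = [s for s, st in zip(matrix.sample_ids, stages) if st == stage_a]
    cols_b = [s for s, st in zip(matrix.sample_ids, stages) if st == stage_b]
    if not cols_a:
        raise ValueError(f"stage {stage_a!r} absent from metadata")
    if not cols_b:
        raise ValueError(f"stage {stage_b!r} absent from metadata")
    max_a = matrix.values[cols_a].max(axis=1)
    max_b = matrix.values[cols_b].max(axis=1)
    on_a = set(matrix.values.index[(max_a >= hi_fpkm) & (max_b < off_fpkm)])
    on_b = set(matrix.values.index[(max_b >= hi_fpkm) & (max_a < off_fpkm)])
    return on_a, on_b


@dataclass
class DensityComparison:
    grid: np.ndarray
    linc_density: np.ndarray
    mrna_density: np.ndarray
    ks_statistic: float
    p_value: float


def density_compare(
    linc_values: Sequence[float], mrna_values: Sequence[float], n_grid: int = 256
) -> DensityComparison:
    """KDE curves on log2(FPKM+1) plus a two-sample KS test.

    Gaussian kernels with Silverman bandwidth; KS D = sup|F1 - F2| with the
    asymptotic p-value.
    """
    a = np.log2(np.asarray(linc_values, dtype=float) + 1.0)
    b = np.log2(np.asarray(mrna_values, dtype=float) + 1.0)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    lo = min(a.min(), b.min()) - 1.0
    hi = max(a.max(), b.max()) + 1.0
    grid = np.linspace(lo, hi, n_grid)
    kde_a = stats.gaussian_kde(a, bw_method="silverman") if np.ptp(a) > 0 else None
    kde_b = stats.gaussian_kde(b, bw_method="silverman") if np.ptp(b) > 0 else None
    dens_a = kde_a(grid) if kde_a else np.zeros_like(grid)
    dens_b = kde_b(grid) if kde_b else np.zeros_like(grid)
    res = stats.ks_2samp(a, b, method="asymp")
    return DensityComparison(grid, dens_a, dens_b, float(res.statistic), float(res.pvalue))


def neighbor_distances(
    lincs: Sequence[TranscriptModel],
    annotation: GenomeAnnotation,
    window: int = 10_000,
    biotype: str | None = "protein_coding",
) -> tuple[list[NeighborResult], float, set[str]]:
    """Nearest protein-coding gene per lincRNA.

    Distance is the gap between the closest interval ends (0 when the
    intervals overlap or abut). Returns per-linc results, the fraction with
    distance < window, and the set of neighbor gene IDs for lincs within the
    window (input to GO enrichment).
    """
    by_chrom = annotation.genes_by_chrom(biotype=biotype)
    results: list[NeighborResult] = []
    neighbor_genes: set[str] = set()
    for t in lincs:
        genes = by_chrom.get(t.chrom)
        if not genes:
            warnings.warn(f"{t.transcript_id}: no annotated genes on {t.chrom}; excluded")
            continue
        best_gene, best_d = None, None
        for g in genes:
            if t.end <= g.start:
                d = g.start - t.end
            elif g.end <= t.start:
                d = t.start - g.end
            else:
                d = 0
            if best_d is None or d < best_d or (d == best_d and g.gene_id < best_gene.gene_id):
                best_gene, best_d = g, d
        results.append(NeighborResult(t.transcript_id, best_gene.gene_id, best_d))
        if best_d < window:
            neighbor_genes.add(best_gene.gene_id)
    fraction = (
        sum(1 for r in results if r.distance_bp < window) / len(results) if results else 0.0
    )
    return results, fraction, neighbor_genes
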