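"""Weighted co-expression network analysis, from scratch.

Soft-threshold adjacency on log2(FPKM+1), topological overlap, deterministic
average-linkage module detection with a static tree cut, module eigengenes,
Spearman module-trait and gene-trait correlation (BH-corrected within
modules), intramodular connectivity, hub calls, and a weighted edge-list
export with lincRNA-hub links.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

# WGCNA's conventional module color sequence; assigned by size rank, with
# "grey" reserved for the unassigned pool.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]
UNASSIGNED = "grey"

DEVELOPMENT_TRAITS = {"time_days", "time_order", "stage_ordinal"}


@dataclass
class NetworkConfig:
    beta: int | str = "auto"
    cor_method_genes: str = "pearson"
    signed: bool = False
    min_module_size: int = 10
    tree_cut_height: float = 0.25
    module_trait_rho_min: float = 0.6
    module_trait_p_max: float = 0.01
    gene_trait_fdr_max: float = 0.05
    hub_percentile: float = 0.05
    edge_export_top_k: int = 100

    def __post_init__(self) -> None:
        if self.beta != "auto" and int(self.beta) < 1:
            raise ValueError("beta must be >= 1 or 'auto'")
        if not 0 < self.hub_percentile < 1:
            raise ValueError("hub_percentile outside (0,1)")


@dataclass
class TraitVector:
    name: str
    values: np.ndarray


@dataclass
class GeneTraitResult:
    feature_id: str
    module: str
    rho: float
    p: float
    p_fdr: float

    @property
    def sign(self) -> str:
        return "+" if self.rho >= 0 else "-"


@dataclass
class CoexpressionModule:
    label: str
    member_ids: list[str]
    eigengene: np.ndarray | None = None
    trait_correlations: dict[str, tuple[float, float]] = field(default_factory=dict)
    flagged_trait_related: bool = False
    intramodular_connectivity: dict[str, float] = field(default_factory=dict)
    hubs: list[str] = field(default_factory=list)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (Pearson on mid-ranks) with the t-approximation p-value.

    Returns (nan, nan) with a warning when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman correlation undefined")
        return (float("nan"), float("nan"))
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _log_standardize(values: pd.DataFrame) -> np.ndarray:
    """log2(FPKM+1) then per-feature z-score; constant features -> zero rows."""
    X = np.log2(values.to_numpy(dtype=float) + 1.0)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant feature(s): correlations set to 0")
    sd[constant] = 1.0
    Z = (X - mu) / sd
    Z[constant] = 0.0
    return Z


def correlation_matrix(values: pd.DataFrame, method: str = "pearson") -> np.ndarray:
    Z = _log_standardize(values)
    if method == "spearman":
        Z = np.apply_along_axis(stats.rankdata, 1, Z)
        Z = (Z - Z.mean(axis=1, keepdims=True))
        norm = np.sqrt((Z**2).sum(axis=1, keepdims=True))
        norm[norm == 0] = 1.0
        Z = Z / norm
        C = Z @ Z.T
    else:
        n = Z.shape[1]
        C = (Z @ Z.T) / n
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    return C


def adjacency(values: pd.DataFrame, config: NetworkConfig, beta: int | None = None) -> np.ndarray:
    """Soft-threshold adjacency: |cor|^beta (unsigned) or ((1+cor)/2)^beta (signed)."""
    if values.shape[1] < 4:
        raise ValueError("need >= 4 samples")
    b = beta if beta is not None else config.beta
    if b == "auto":
        b = pick_soft_power(values, config=config)
    C = correlation_matrix(values, config.cor_method_genes)
    A = ((1.0 + C) / 2.0) ** int(b) if config.signed else np.abs(C) ** int(b)
    np.fill_diagonal(A, 1.0)
    return A


def scale_free_fit(A: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the linear fit of log10 p(k) vs log10 k over occupied bins."""
    k = A.sum(axis=0) - 1.0
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    mask = (counts > 0) & (centers > 0)
    if mask.sum() < 8:
        return 0.0
    x = np.log10(centers[mask])
    y = np.log10(counts[mask] / counts.sum())
    if np.ptp(x) == 0:
        return 0.0
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    return 1.0 - float((resid**2).sum()) / ss_tot


def pick_soft_power(
    values: pd.DataFrame,
    candidates: Sequence[int] = tuple(range(1, 21)),
    r2_min: float = 0.8,
    config: NetworkConfig | None = None,
) -> int:
    """Smallest power whose connectivity distribution fits scale-free R^2 >= r2_min.

    Falls back to 6 with a warning when no candidate qualifies.
    """
    cfg = config or NetworkConfig()
    C = correlation_matrix(values, cfg.cor_method_genes)
    for b in candidates:
        A = ((1.0 + C) / 2.0) ** b if cfg.signed else np.abs(C) ** b
        np.fill_diagonal(A, 1.0)
        if scale_free_fit(A) >= r2_min:
            return int(b)
    warnings.warn("no soft power reached the scale-free fit target; falling back to 6")
    return 6


def topological_overlap(A: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u A_iu A_uj + A_ij) / (min(k_i,k_j) + 1 - A_ij); TOM_ii = 1."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    numerator = A0 @ A0 + A0
    denominator = np.minimum.outer(k, k) + 1.0 - A0
    tom = numerator / denominator
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    tom: np.ndarray, feature_ids: Sequence[str], config: NetworkConfig
) -> dict[str, str]:
    """Average-linkage clustering on 1-TOM with a static tree cut.

    Clusters smaller than min_module_size fall into the "grey" unassigned
    pool; surviving clusters get color labels by decreasing size (ties:
    order of first member appearance).
    """
    n = len(feature_ids)
    if n != tom.shape[0]:
        raise ValueError("feature_ids length does not match TOM")
    if n < config.min_module_size:
        return {fid: UNASSIGNED for fid in feature_ids}
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(np.clip(dissim, 0.0, None), checks=False)
    Z = linkage(condensed, method="average")
    raw = fcluster(Z, t=config.tree_cut_height, criterion="distance")
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(raw):
        groups.setdefault(int(lab), []).append(idx)
    sized = [
        (len(members), min(members), lab)
        for lab, members in groups.items()
        if len(members) >= config.min_module_size
    ]
    sized.sort(key=lambda t: (-t[0], t[1]))
    assignment = {fid: UNASSIGNED for fid in feature_ids}
    for color_idx, (_, _, lab) in enumerate(sized):
        color = (
            MODULE_COLORS[color_idx]
            if color_idx < len(MODULE_COLORS)
            else f"module{color_idx + 1}"
        )
        for i in groups[lab]:
            assignment[feature_ids[i]] = color
    return assignment


def module_eigengene(values: pd.DataFrame) -> np.ndarray:
    """First principal component (unit norm) of a module's standardized submatrix.

    The sign is oriented so the eigengene correlates non-negatively with the
    members' mean standardized profile.
    """
    if values.shape[0] < 2:
        raise ValueError("module needs >= 2 members")
    Z = _log_standardize(values)
    if not np.any(Z):
        raise ValueError("degenerate (rank-0) module submatrix")
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    eig = vt[0]
    mean_profile = Z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return eig / np.linalg.norm(eig)


def module_trait(
    modules: Sequence[CoexpressionModule],
    traits: Sequence[TraitVector],
    config: NetworkConfig,
) -> None:
    """Spearman correlation of every module eigengene with every trait.

    A module is flagged trait-related when |rho| >= rho_min and p < p_max
    for at least one development-time trait. Mutates the modules in place.
    """
    for mod in modules:
        if mod.eigengene is None:
            continue
        flagged = False
        for trait in traits:
            if len(trait.values) != len(mod.eigengene):
                raise ValueError(f"trait {trait.name}: length mismatch with eigengene")
            rho, p = spearman(mod.eigengene, trait.values)
            mod.trait_correlations[trait.name] = (rho, p)
            if (
                trait.name in DEVELOPMENT_TRAITS
                and not math.isnan(rho)
                and abs(rho) >= config.module_trait_rho_min
                and p < config.module_trait_p_max
            ):
                flagged = True
        mod.flagged_trait_related = flagged


def gene_trait(
    values: pd.DataFrame,
    trait: TraitVector,
    module_assignment: Mapping[str, str],
    config: NetworkConfig,
    global_fdr: bool = False,
) -> list[GeneTraitResult]:
    """Per-feature Spearman vs a trait with BH correction within each module."""
    rows: list[tuple[str, str, float, float]] = []
    for fid in values.index:
        rho, p = spearman(values.loc[fid].to_numpy(), trait.values)
        rows.append((fid, module_assignment.get(fid, UNASSIGNED), rho, p))
    results: list[GeneTraitResult] = []
    if global_fdr:
        scopes = {"all": rows}
    else:
        scopes = {}
        for row in rows:
            scopes.setdefault(row[1], []).append(row)
    for scope_rows in scopes.values():
        valid = [r for r in scope_rows if not math.isnan(r[3])]
        if valid:
            _, p_adj, _, _ = multipletests([r[3] for r in valid], method="fdr_bh")
        for r in scope_rows:
            if math.isnan(r[3]):
                results.append(GeneTraitResult(r[0], r[1], r[2], r[3], float("nan")))
            else:
                idx = valid.index(r)
                results.append(GeneTraitResult(r[0], r[1], r[2], r[3], float(p_adj[idx])))
    results.sort(key=lambda g: g.feature_id)
    return results


def intramodular_connectivity(
    A: np.ndarray, feature_ids: Sequence[str], module_assignment: Mapping[str, str]
) -> dict[str, float]:
    """kIM_i: summed adjacency to same-module members (diagonal excluded)."""
    index = {fid: i for i, fid in enumerate(feature_ids)}
    kim: dict[str, float] = {}
    by_module: dict[str, list[str]] = {}
    for fid in feature_ids:
        by_module.setdefault(module_assignment.get(fid, UNASSIGNED), []).append(fid)
    for label, members in by_module.items():
        idx = np.array([index[m] for m in members])
        sub = A[np.ix_(idx, idx)]
        sums = sub.sum(axis=1) - 1.0  # exclude self-adjacency
        for m, s in zip(members, sums):
            kim[m] = float(s)
    return kim


def hubs_and_links(
    A: np.ndarray,
    feature_ids: Sequence[str],
    module_assignment: Mapping[str, str],
    linc_ids: set[str],
    config: NetworkConfig,
) -> tuple[dict[str, list[str]], list[tuple[str, str, str, float]], set[str]]:
    """Hub calls plus the exported edge list and lincRNA-hub links.

    Hubs are the top ceil(hub_percentile * module size) members by
    intramodular connectivity (ties by ID). Per module the strongest
    edge_export_top_k edges are exported; a lincRNA counts as hub-linked
    when one of those edges joins it to a hub.
    """
    index = {fid: i for i, fid in enumerate(feature_ids)}
    kim = intramodular_connectivity(A, feature_ids, module_assignment)
    hubs: dict[str, list[str]] = {}
    edges: list[tuple[str, str, str, float]] = []
    linked_lincs: set[str] = set()
    by_module: dict[str, list[str]] = {}
    for fid in feature_ids:
        label = module_assignment.get(fid, UNASSIGNED)
        if label != UNASSIGNED:
            by_module.setdefault(label, []).append(fid)
    for label in sorted(by_module):
        members = by_module[label]
        n_hubs = math.ceil(config.hub_percentile * len(members))
        ranked = sorted(members, key=lambda m: (-kim[m], m))
        hubs[label] = ranked[:n_hubs]
        hub_set = set(hubs[label])
        module_edges = []
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                w = float(A[index[a], index[b]])
                module_edges.append((w, *sorted((a, b))))
        module_edges.sort(key=lambda e: (-e[0], e[1], e[2]))
        for w, a, b in module_edges[: config.edge_export_top_k]:
            edges.append((label, a, b, w))
            for x, y in ((a, b), (b, a)):
                if x in linc_ids and y in hub_set:
                    linked_lincs.add(x)
    return hubs, edges, linked_lincs


@dataclass
class NetworkResult:
    beta: int
    adjacency: np.ndarray
    tom: np.ndarray
    feature_ids: list[str]
    module_assignment: dict[str, str]
    modules: list[CoexpressionModule]
    gene_trait_results: list[GeneTraitResult]
    hubs: dict[str, list[str]]
    edges: list[tuple[str, str, str, float]]
    linked_lincs: set[str]


def build_network(
    values: pd.DataFrame,
    traits: Sequence[TraitVector],
    config: NetworkConfig | None = None,
    linc_ids: set[str] | None = None,
    gene_trait_name: str = "time_order",
) -> NetworkResult:
    """End-to-end network construction on an FPKM (features x samples) frame."""
    config = config or NetworkConfig()
    beta = config.beta if config.beta != "auto" else pick_soft_power(values, config=config)
    A = adjacency(values, config, beta=int(beta))
    tom = topological_overlap(A)
    feature_ids = list(values.index)
    assignment = detect_modules(tom, feature_ids, config)
    labels = sorted(
        {lab for lab in assignment.values() if lab != UNASSIGNED},
        key=lambda lab: (-sum(1 for v in assignment.values() if v == lab), lab),
    )
    modules = []
    for lab in labels:
        members = [fid for fid in feature_ids if assignment[fid] == lab]
        mod = CoexpressionModule(label=lab, member_ids=members)
        mod.eigengene = module_eigengene(values.loc[members])
        modules.append(mod)
    module_trait(modules, traits, config)
    trait_by_name = {t.name: t for t in traits}
    gt_trait = trait_by_name.get(gene_trait_name, traits[0] if traits else None)
    gene_results = (
        gene_trait(values, gt_trait, assignment, config) if gt_trait is not None else []
    )
    hubs, edges, linked = hubs_and_links(
        A, feature_ids, assignment, linc_ids or set(), config
    )
    kim = intramodular_connectivity(A, feature_ids, assignment)
    for mod in modules:
        mod.intramodular_connectivity = {m: kim[m] for m in mod.member_ids}
        mod.hubs = hubs.get(mod.label, [])
    return NetworkResult(
        beta=int(beta),
        adjacency=A,
        tom=tom,
        feature_ids=feature_ids,
        module_assignment=assignment,
        modules=modules,
        gene_trait_results=gene_results,
        hubs=hubs,
        edges=edges,
        linked_lincs=linked,
    )
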