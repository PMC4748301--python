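"""Fixed hexamer model separating coding from noncoding sequence.

The coding model treats an in-frame hexamer as a pair of adjacent codons and
assigns it the product of the two codon probabilities under a fixed,
positionally biased codon-usage table (strong purine preference at codon
position 1, pyrimidine/GC skew at position 3 — the classic signature that
hexamer-based coding-potential classifiers exploit). The noncoding
model is a product of single-base frequencies with mild AT richness. The
log2 ratio table over all 4096 hexamers is what the coding-potential score
consumes; the synthetic-data generator draws its coding ORFs from the same
codon table, so the two halves of the package share one generative story.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product
from math import log2

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODON = "ATG"

# Positional base weights inside coding codons.
_POS1 = {"A": 0.30, "C": 0.17, "G": 0.35, "T": 0.18}
_POS2 = {"A": 0.31, "C": 0.23, "G": 0.17, "T": 0.29}
_POS3 = {"A": 0.13, "C": 0.33, "G": 0.35, "T": 0.19}

# Residual probability mass assigned to each stop codon inside the coding
# model (stops are absent from real ORF interiors but the model must remain
# strictly positive over all hexamers).
_STOP_WEIGHT = 1e-3

# Noncoding background: mildly AT-rich, matching the simulator's intergenic
# base composition.
NONCODING_BASE_FREQS = {"A": 0.30, "C": 0.20, "G": 0.20, "T": 0.30}


@lru_cache(maxsize=1)
def codon_probabilities() -> dict[str, float]:
    """Coding-model codon distribution (stops down-weighted, sums to 1)."""
    raw = {}
    for c1, c2, c3 in product(BASES, repeat=3):
        codon = c1 + c2 + c3
        w = _POS1[c1] * _POS2[c2] * _POS3[c3]
        if codon in STOP_CODONS:
            w = _STOP_WEIGHT
        raw[codon] = w
    total = sum(raw.values())
    return {c: w / total for c, w in raw.items()}


@lru_cache(maxsize=1)
def interior_codon_distribution() -> tuple[tuple[str, ...], tuple[float, ...]]:
    """Codon distribution conditioned on not being a stop (for ORF interiors)."""
    probs = codon_probabilities()
    codons = tuple(c for c in sorted(probs) if c not in STOP_CODONS)
    mass = sum(probs[c] for c in codons)
    return codons, tuple(probs[c] / mass for c in codons)


@lru_cache(maxsize=1)
def hexamer_log_ratios() -> dict[str, float]:
    """log2(f_coding / f_noncoding) for every ACGT hexamer."""
    probs = codon_probabilities()
    table: dict[str, float] = {}
    for c1 in probs:
        for c2 in probs:
            hexamer = c1 + c2
            f_coding = probs[c1] * probs[c2]
            f_noncoding = 1.0
            for b in hexamer:
                f_noncoding *= NONCODING_BASE_FREQS[b]
            table[hexamer] = log2(f_coding / f_noncoding)
    return table
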