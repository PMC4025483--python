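"""Eigengene decomposition of expression time courses.

A genes × timepoints matrix D is factored by singular value decomposition,

    D = U S Vᵀ,

which maps the data from (transcript) × (time) space to (eigengene) ×
(eigentime) space.  Each row of Vᵀ is an *eigengene*: a unit-norm temporal
pattern shared across genes.  Column i of U holds each gene's loading on
eigengene i.  The share of overall expression captured by eigengene i is
its *eigenexpression fraction*

    eᵢ = sᵢ / Σⱼ sⱼ,

with s the singular values taken linearly, and the order in the spectrum
is summarised by the normalised Shannon entropy

    d = −(1 / ln n) Σᵢ eᵢ ln eᵢ,  0 ≤ d ≤ 1,

where d = 0 means one pattern carries everything (fully ordered) and
d = 1 means all patterns contribute equally (fully unordered).

Signs of singular vectors are arbitrary; each eigengene is oriented so
that its largest-magnitude timepoint is positive, with the matching U
column flipped in tandem, so loadings and patterns stay consistent and
runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionMatrix

__all__ = [
    "EigenDecomposition",
    "RankedGeneList",
    "decompose",
    "eigenexpression_fractions",
    "shannon_entropy",
    "cumulative_fraction",
    "rank_genes",
]

_SUM_TOL = 1e-8


@dataclass(frozen=True)
class EigenDecomposition:
    """Thin SVD of an expression matrix, with derived spectrum statistics.

    ``loadings`` is U (genes × r), ``eigengenes`` is Vᵀ (r × timepoints)
    and ``singular_values`` the diagonal of S, sorted descending.  r equals
    the number of timepoints; zero singular values are retained so the
    pattern count always matches the timepoint count.
    """

    loadings: np.ndarray = field(repr=False)
    singular_values: np.ndarray
    eigengenes: np.ndarray = field(repr=False)
    fractions: np.ndarray
    entropy: float
    orientation_signs: np.ndarray
    gene_ids: list[str] = field(repr=False)
    stage_labels: list[str]

    @property
    def n_patterns(self) -> int:
        return len(self.singular_values)


def decompose(
    matrix: ExpressionMatrix,
    transform: str = "none",
    center: bool = False,
) -> EigenDecomposition:
    """Full thin SVD of an expression time course.

    Parameters
    ----------
    matrix
        Gene × timepoint abundances; must have at least as many genes as
        timepoints so the decomposition spans time space.
    transform
        ``"none"`` (default) or ``"log1p"``.  By default values enter the
        SVD untransformed: with raw nonnegative abundances the leading
        eigengene is the roughly constant baseline expression pattern.
    center
        If True, subtract each gene's mean across timepoints before the
        SVD.  This removes the constant pattern and focuses the spectrum
        on temporal change; off by default.

    Returns
    -------
    EigenDecomposition
        With r = number of timepoints patterns, oriented signs, fractions
        and entropy populated.
    """
    if transform not in ("none", "log1p"):
        raise ValueError(f"unknown transform {transform!r}; use 'none' or 'log1p'")
    n_genes, n_time = matrix.values.shape
    if n_genes < n_time:
        raise ValueError(
            f"matrix has {n_genes} genes but {n_time} timepoints; "
            "a full decomposition of time space needs at least as many genes "
            "as timepoints"
        )
    data = matrix.values
    if transform == "log1p":
        data = np.log1p(data)
    if center:
        data = data - data.mean(axis=1, keepdims=True)

    u, s, vt = np.linalg.svd(data, full_matrices=False)

    # orient: largest-|value| timepoint of each eigengene made positive
    signs = np.ones(len(s))
    for i in range(len(s)):
        peak = np.argmax(np.abs(vt[i]))
        if vt[i, peak] < 0:
            signs[i] = -1.0
    vt = vt * signs[:, None]
    u = u * signs[None, :]

    if np.allclose(s, 0.0):
        raise ValueError("all-zero matrix has no eigengene spectrum")
    fractions = eigenexpression_fractions(s)
    entropy = shannon_entropy(fractions)
    return EigenDecomposition(
        loadings=u,
        singular_values=s,
        eigengenes=vt,
        fractions=fractions,
        entropy=entropy,
        orientation_signs=signs,
        gene_ids=list(matrix.gene_ids),
        stage_labels=list(matrix.stage_labels),
    )


def eigenexpression_fractions(singular_values: np.ndarray) -> np.ndarray:
    """Fractional abundance of each pattern: eᵢ = sᵢ / Σⱼ sⱼ.

    Singular values enter linearly, not squared, so the fractions
    apportion the singular-value spectrum itself.
    """
    s = np.asarray(singular_values, dtype=float)
    if s.ndim != 1 or len(s) == 0:
        raise ValueError("singular_values must be a nonempty 1-D array")
    if np.any(s < 0):
        raise ValueError("singular values must be nonnegative")
    total = s.sum()
    if total == 0:
        raise ValueError("all singular values are zero")
    return s / total


def shannon_entropy(fractions: np.ndarray) -> float:
    """Normalised Shannon entropy d of the eigenexpression fractions.

    d = −(1/ln n) Σ eᵢ ln eᵢ with 0·ln 0 := 0.  d = 0 for a degenerate
    spectrum (one nonzero fraction), d = 1 for a uniform one.
    """
    e = np.asarray(fractions, dtype=float)
    if e.ndim != 1 or len(e) < 2:
        raise ValueError("need at least 2 fractions")
    if np.any(e < 0):
        raise ValueError("fractions must be nonnegative")
    if abs(e.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"fractions sum to {e.sum():.12g}, expected 1")
    nz = e[e > 0]
    d = -float(np.sum(nz * np.log(nz))) / np.log(len(e))
    return float(min(max(d, 0.0), 1.0))


def cumulative_fraction(fractions: np.ndarray, top_k: int) -> float:
    """Sum of the ``top_k`` largest eigenexpression fractions."""
    e = np.asarray(fractions, dtype=float)
    if not 1 <= top_k <= len(e):
        raise ValueError(f"top_k={top_k} out of range 1..{len(e)}")
    return float(np.sort(e)[::-1][:top_k].sum())


@dataclass(frozen=True)
class RankedGeneList:
    """Genes ordered by descending loading on one eigengene pattern.

    ``pattern_index`` is 1-based (pattern 1 = largest singular value).
    Ties in loading are broken lexicographically by gene ID.
    """

    pattern_index: int
    entries: list[tuple[str, float]]

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def rank_genes(
    decomp: EigenDecomposition,
    pattern_index: int,
    top_n: int = 500,
) -> RankedGeneList:
    """Top-N genes by signed, oriented loading on one pattern.

    The relevant U column is sorted in descending order (after sign
    orientation) and truncated to ``top_n`` entries; these are the genes
    most closely associated with that eigengene.
    """
    if not 1 <= pattern_index <= decomp.n_patterns:
        raise ValueError(
            f"pattern_index={pattern_index} out of range 1..{decomp.n_patterns}"
        )
    if not 1 <= top_n <= len(decomp.gene_ids):
        raise ValueError(f"top_n={top_n} out of range 1..{len(decomp.gene_ids)}")
    col = decomp.loadings[:, pattern_index - 1]
    ids = np.array(decomp.gene_ids)
    # stable sort on gene ID first, then on -loading, gives the
    # descending-by-loading, lexicographic-tie order deterministically
    order = np.lexsort((ids, -col))
    top = order[:top_n]
    entries = [(str(ids[i]), float(col[i])) for i in top]
    return RankedGeneList(pattern_index=pattern_index, entries=entries)
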