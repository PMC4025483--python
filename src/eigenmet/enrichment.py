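"""Hypergeometric over-representation test for annotated gene catalogs.

Given a universe of M genes of which K carry an annotation (e.g. "metabolic
gene"), and a selection of m genes of which k are annotated, the upper-tail
probability of seeing at least k annotated genes by chance is

    P(X ≥ k) = Σ_{i=k}^{min(K, m)}  C(K, i) C(M−K, m−i) / C(M, m).

The sum is evaluated in log-space via log-gamma so that probabilities
down to ~1e-20 and beyond are computed without underflow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.special import gammaln, logsumexp

from .eigengenes import RankedGeneList

__all__ = ["AnnotationCatalog", "EnrichmentResult", "hypergeom_tail", "enrich", "read_catalog"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationCatalog:
    """A gene universe and the annotated subset to test for enrichment."""

    universe: frozenset[str]
    annotated: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "universe", frozenset(self.universe))
        object.__setattr__(self, "annotated", frozenset(self.annotated))
        if not self.annotated <= self.universe:
            extra = sorted(self.annotated - self.universe)[:3]
            raise ValueError(
                f"annotated genes not in universe (e.g. {extra}); "
                "the catalog must be a subset of the universe"
            )

    @property
    def M(self) -> int:
        return len(self.universe)

    @property
    def K(self) -> int:
        return len(self.annotated)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric tail test outcome.

    M: universe size; K: annotated genes in the universe; m: selection
    size; k: annotated genes in the selection; p_value: P(X ≥ k).
    """

    M: int
    K: int
    m: int
    k: int
    p_value: float
    log10_p: float
    label: str = ""

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "M": self.M,
            "K": self.K,
            "m": self.m,
            "k": self.k,
            "p_value": self.p_value,
            "log10_p": self.log10_p,
        }


def _log_pmf(M: int, K: int, m: int, i) -> float:
    """ln P(X = i) for X ~ Hypergeometric(M, K, m), via log-gamma."""

    def lchoose(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    return lchoose(K, i) + lchoose(M - K, m - i) - lchoose(M, m)


def hypergeom_tail(M: int, K: int, m: int, k: int, label: str = "") -> EnrichmentResult:
    """Upper-tail hypergeometric probability P(X ≥ k).

    Summation runs from k to min(K, m); terms outside the support
    (i > K or m − i > M − K) are identically zero and omitted.  Evaluated
    in log-space so values far below double-precision underflow of a
    naive product (e.g. 1e-20) remain accurate.
    """
    for name, val in (("M", M), ("K", K), ("m", m), ("k", k)):
        if int(val) != val or val < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {val!r}")
    M, K, m, k = int(M), int(K), int(m), int(k)
    if K > M:
        raise ValueError(f"K={K} exceeds M={M}")
    if m > M:
        raise ValueError(f"m={m} exceeds M={M}")
    if k > m:
        raise ValueError(f"k={k} exceeds m={m}")

    lo = max(k, m - (M - K))  # below lo, m−i > M−K: zero mass
    hi = min(K, m)
    if k <= max(0, m - (M - K)):
        # the tail covers the whole support: exactly 1, no summation noise
        return EnrichmentResult(M, K, m, k, 1.0, 0.0, label)
    if lo > hi:
        # demanding more annotated draws than the catalog can supply:
        # the event is impossible; clamp into (0, 1]
        return EnrichmentResult(M, K, m, k, math.nextafter(0.0, 1.0), -math.inf, label)
    i = np.arange(lo, hi + 1)
    log_p = float(logsumexp(_log_pmf(M, K, m, i)))
    p = min(math.exp(log_p), 1.0)
    if p == 0.0:
        p = math.nextafter(0.0, 1.0)  # clamp to (0, 1]
    return EnrichmentResult(M, K, m, k, p, log_p / math.log(10.0), label)


def enrich(
    selection: RankedGeneList | Iterable[str],
    catalog: AnnotationCatalog,
) -> EnrichmentResult:
    """Test a gene selection for over-representation of the catalog.

    ``selection`` may be a ranked gene list (its gene IDs are used) or any
    iterable of gene IDs.  Genes outside the catalog universe are dropped
    with a warning; m and k are counted on the filtered selection.
    """
    if isinstance(selection, RankedGeneList):
        genes = set(selection.gene_ids)
    else:
        genes = set(selection)
    outside = genes - catalog.universe
    if outside:
        logger.warning(
            "%d of %d selected genes are outside the universe and were dropped",
            len(outside),
            len(genes),
        )
        genes -= outside
    if not genes:
        raise ValueError("selection is empty after restricting to the universe")
    m = len(genes)
    k = len(genes & catalog.annotated)
    return hypergeom_tail(catalog.M, catalog.K, m, k, label=catalog.label)


def read_catalog(
    path: str | Path,
    universe: Iterable[str],
    label: str = "",
) -> AnnotationCatalog:
    """Read an annotated-gene list (one gene per line, or gene<TAB>label).

    Genes in the file but absent from the universe are dropped with a
    warning, mirroring ID-reconciliation losses in real catalogs.
    """
    universe = frozenset(str(g) for g in universe)
    annotated: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        annotated.add(line.split("\t")[0])
    missing = annotated - universe
    if missing:
        logger.warning(
            "%d catalog genes absent from the universe were dropped", len(missing)
        )
    return AnnotationCatalog(universe=universe, annotated=frozenset(annotated & universe), label=label)
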