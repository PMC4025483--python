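"""Synthetic staged-embryo datasets with known ground truth.

Every analysis stage in this package can be exercised without external
downloads: this module plants low-rank temporal patterns in an expression
matrix, enrichment signal in an annotation catalog, and fold-change
trajectories in replicated GC-MS-style peak tables and nutrient-store
assays, and returns the planted truth alongside each dataset so recovery
can be scored.

Default dimensions mirror a staged embryonic study: 17,000 genes × 12
two-hour bins for expression, ~100 metabolites × 12 bins × 7 replicate
sample sets for the metabolome, and 6 replicates per bin for stores.
All dimensions scale down to seconds-scale test sizes.

Noise models: additive Gaussian on expression values (clipped at zero),
matching RPKM-scale scatter; multiplicative lognormal on peak areas,
matching GC-MS error; a per-sample lognormal injection factor applied to
every peak *and* to the internal standard, so internal-standard
normalization cancels it exactly.  Planted time patterns are mutually
orthogonalized before mixing — a deliberate idealization that makes them
identifiable by SVD.  All randomness comes from ``numpy``'s PCG64
generator seeded explicitly, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import AnnotationCatalog
from .expression import ExpressionMatrix, stage_labels_2h
from .metabolomics import INTERNAL_STANDARD_COLUMN, MetaboliteTimecourse, StoreAssay

__all__ = [
    "PatternSpec",
    "ExpressionSimSpec",
    "TrajectorySpec",
    "MetabolomeSimSpec",
    "StoreSimSpec",
    "SyntheticTruth",
    "generate_expression",
    "generate_annotations",
    "generate_metabolome",
    "generate_stores",
    "ratio_for_expected_overlap",
    "example_trajectories",
]


# ---------------------------------------------------------------------------
# expression

def _pattern_shape(shape, n_timepoints: int) -> np.ndarray:
    """Raw (un-orthogonalized) temporal template for a named shape."""
    t = np.linspace(0.0, 1.0, n_timepoints)
    if isinstance(shape, (list, tuple, np.ndarray)):
        v = np.asarray(shape, dtype=float)
        if len(v) != n_timepoints:
            raise ValueError(
                f"custom pattern has length {len(v)}, expected {n_timepoints}"
            )
        return v
    if shape == "constant":
        return np.ones(n_timepoints)
    if shape == "step_up_mid":
        # broad upregulation midway through the series
        return 1.0 / (1.0 + np.exp(-12.0 * (t - 0.5)))
    if shape == "u_shape":
        # dips mid-series, recovers late
        return np.cos(2.0 * np.pi * t)
    raise ValueError(f"unknown pattern shape {shape!r}")


@dataclass(frozen=True)
class PatternSpec:
    """One planted temporal pattern.

    ``shape`` is a named template or a custom vector; ``weight`` scales
    its contribution; ``member_fraction`` is the fraction of genes that
    load on it (membership for non-constant patterns is disjoint).
    """

    shape: str | Sequence[float]
    weight: float
    member_fraction: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("pattern weight must be > 0")
        if not 0 < self.member_fraction <= 1:
            raise ValueError("member_fraction must be in (0, 1]")


def _default_patterns() -> list[PatternSpec]:
    return [
        PatternSpec("constant", weight=30.0, member_fraction=1.0),
        PatternSpec("step_up_mid", weight=12.0, member_fraction=0.2),
        PatternSpec("u_shape", weight=8.0, member_fraction=0.1),
    ]


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Parameters of the planted low-rank expression simulation."""

    n_genes: int = 17000
    n_timepoints: int = 12
    patterns: list[PatternSpec] = field(default_factory=_default_patterns)
    noise_sd: float = 0.25
    baseline_offset: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.n_timepoints:
            raise ValueError("need at least as many genes as timepoints")
        if self.n_timepoints < 2:
            raise ValueError("need ≥2 timepoints")
        if self.noise_sd < 0 or self.baseline_offset < 0:
            raise ValueError("noise_sd and baseline_offset must be ≥ 0")
        if not self.patterns and self.noise_sd == 0:
            raise ValueError("degenerate spec: no patterns and no noise")


@dataclass
class SyntheticTruth:
    """Planted ground truth, sufficient to score recovery.

    Filled incrementally: :func:`generate_expression` populates the
    pattern/loading fields, :func:`generate_annotations` the enrichment
    fields, and the metabolome/store generators the trajectory fields.
    """

    gene_ids: list[str] | None = None
    patterns: np.ndarray | None = None          # r × timepoints, orthonormal rows
    loadings: np.ndarray | None = None          # genes × r
    weights: np.ndarray | None = None
    member_masks: np.ndarray | None = None      # r × genes booleans
    snr: np.ndarray | None = None               # per-pattern signal-to-noise
    annotated: frozenset[str] | None = None
    enrichment_target_pattern: int | None = None
    requested_enrichment_ratio: float | None = None
    realized_enrichment_ratio: float | None = None
    true_trajectories: dict[str, np.ndarray] | None = None
    store_trajectories: dict[str, np.ndarray] | None = None


def generate_expression(spec: ExpressionSimSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a genes × timepoints matrix from planted patterns.

    The matrix is ``baseline_offset + Σₚ weightₚ · loadingsₚ ⊗ patternₚ +
    N(0, noise_sd²)``, clipped at zero.  Temporal patterns are
    orthonormalized (QR) in the order given; gene membership of the
    non-constant patterns is disjoint, so each planted component is close
    to a true singular triplet.  The per-pattern signal-to-noise ratio
    ``weightₚ·‖loadingsₚ‖ / (noise_sd·√n_genes)`` is recorded in the truth.
    """
    rng = np.random.default_rng(spec.seed)
    G, T = spec.n_genes, spec.n_timepoints
    gene_ids = [f"gene{i:05d}" for i in range(G)]
    r = len(spec.patterns)

    raw = np.column_stack([_pattern_shape(p.shape, T) for p in spec.patterns]) if r else np.zeros((T, 0))
    if r:
        q, _ = np.linalg.qr(raw)
        if np.linalg.matrix_rank(raw) < r:
            raise ValueError("planted pattern shapes are linearly dependent")
        # orient like the decomposition: largest-|value| timepoint positive
        for j in range(r):
            if q[np.argmax(np.abs(q[:, j])), j] < 0:
                q[:, j] = -q[:, j]
        patterns = q.T  # r × T, orthonormal rows
    else:
        patterns = np.zeros((0, T))

    loadings = np.zeros((G, r))
    member = np.zeros((r, G), dtype=bool)
    perm = rng.permutation(G)  # disjoint membership pool for non-constant patterns
    cursor = 0
    for j, p in enumerate(spec.patterns):
        n_mem = max(1, int(round(p.member_fraction * G)))
        if _is_constant(p.shape):
            # constant-pattern members come from the end of the pool so a
            # partial constant membership cannot collide with the disjoint
            # non-constant pools taken from the front
            idx = np.arange(G) if p.member_fraction == 1.0 else perm[G - n_mem:]
        else:
            if cursor + n_mem > G:
                raise ValueError("pattern member fractions exceed the gene pool")
            idx = perm[cursor:cursor + n_mem]
            cursor += n_mem
        member[j, idx] = True
        loadings[idx, j] = rng.lognormal(mean=0.0, sigma=0.5, size=len(idx))

    signal = loadings @ (np.array([p.weight for p in spec.patterns])[:, None] * patterns) if r else np.zeros((G, T))
    values = spec.baseline_offset + signal
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=(G, T))
    values = np.clip(values, 0.0, None)

    weights = np.array([p.weight for p in spec.patterns])
    norms = np.linalg.norm(loadings, axis=0)
    noise_scale = spec.noise_sd * np.sqrt(G) if spec.noise_sd > 0 else np.nan
    snr = weights * norms / noise_scale if spec.noise_sd > 0 else np.full(r, np.inf)

    matrix = ExpressionMatrix(
        gene_ids=gene_ids, stage_labels=stage_labels_2h(T), values=values
    )
    truth = SyntheticTruth(
        gene_ids=gene_ids,
        patterns=patterns,
        loadings=loadings,
        weights=weights,
        member_masks=member,
        snr=snr,
    )
    return matrix, truth


def _is_constant(shape) -> bool:
    return isinstance(shape, str) and shape == "constant"


# ---------------------------------------------------------------------------
# annotations

def ratio_for_expected_overlap(M: int, K: int, m: int, k: float) -> float:
    """Oversampling ratio giving expected overlap k of the top-m list.

    Inverts E[k] = K·m·r / (m·r + M − m) for the weighted-sampling scheme
    used by :func:`generate_annotations`.
    """
    if not 0 < k < min(K, m):
        raise ValueError(f"target overlap k={k} infeasible for K={K}, m={m}")
    return k * (M - m) / (m * (K - k))


def generate_annotations(
    truth: SyntheticTruth,
    K: int,
    ratio: float,
    target_pattern: int = 2,
    m: int = 500,
    seed: int = 0,
    label: str = "metabolic genes",
) -> AnnotationCatalog:
    """Plant an annotation catalog enriched among high-loading genes.

    The universe is the simulated gene set (size M).  The K annotated
    genes are drawn without replacement with sampling weight ``ratio``
    for the m genes with the highest planted loadings on
    ``target_pattern`` (1-based) and weight 1 elsewhere, so the expected
    top-m overlap is K·m·ratio / (m·ratio + M − m).  The realized
    enrichment ratio (observed overlap density over the null density
    K·m/M) is recorded in the truth.
    """
    if truth.gene_ids is None or truth.loadings is None:
        raise ValueError("truth lacks expression fields; run generate_expression first")
    if ratio < 1:
        raise ValueError("enrichment ratio must be ≥ 1")
    M = len(truth.gene_ids)
    if K > M:
        raise ValueError(f"K={K} exceeds universe size M={M}")
    expected_k = K * m * ratio / (m * ratio + M - m)
    if expected_k > m:
        raise ValueError(
            f"infeasible ratio: expected overlap {expected_k:.0f} exceeds m={m}"
        )
    rng = np.random.default_rng(seed)
    load = truth.loadings[:, target_pattern - 1]
    top_m = np.argsort(-load, kind="stable")[:m]
    weights = np.ones(M)
    weights[top_m] = ratio
    p = weights / weights.sum()
    chosen = rng.choice(M, size=K, replace=False, p=p)
    gene_arr = np.asarray(truth.gene_ids)
    annotated = frozenset(gene_arr[chosen])

    k_real = len(annotated & set(gene_arr[top_m]))
    truth.annotated = annotated
    truth.enrichment_target_pattern = target_pattern
    truth.requested_enrichment_ratio = ratio
    truth.realized_enrichment_ratio = (k_real / m) / (K / M)
    return AnnotationCatalog(
        universe=frozenset(gene_arr), annotated=annotated, label=label
    )


# ---------------------------------------------------------------------------
# metabolome

@dataclass(frozen=True)
class TrajectorySpec:
    """Planted relative-abundance profile for one metabolite.

    ``fold`` is the final level relative to baseline for rises/drops, the
    mid-series depth for ``u_shape`` and ``early_drop_late_rise``.
    """

    name: str
    shape: str = "flat"
    fold: float = 1.0

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be > 0")
        if self.shape not in (
            "flat", "fold_rise", "fold_drop", "u_shape", "early_drop_late_rise"
        ):
            raise ValueError(f"unknown trajectory shape {self.shape!r}")

    def trajectory(self, n_timepoints: int) -> np.ndarray:
        T = n_timepoints
        traj = np.ones(T)
        if self.shape == "flat":
            return traj
        if self.shape == "fold_rise":
            # rises from the quarter-point on, geometric ramp to `fold`
            start = T // 4
            ramp = np.linspace(0.0, 1.0, T - start)
            traj[start:] = self.fold ** ramp
            return traj
        if self.shape == "fold_drop":
            # stable, then steps down past the midpoint and stays
            change = int(np.ceil(T * 7 / 12))
            traj[change:] = self.fold
            return traj
        if self.shape == "u_shape":
            w = np.sin(np.linspace(0.0, np.pi, T)) ** 2
            return self.fold ** w
        # early_drop_late_rise: sharp drop to `fold` by the sixth of the
        # series, geometric recovery to baseline by the end
        drop_at = max(1, T // 6)
        traj[:drop_at] = 1.0
        recover = np.linspace(1.0, 0.0, T - drop_at)
        traj[drop_at:] = self.fold ** recover
        return traj


def example_trajectories() -> list[TrajectorySpec]:
    """Presets spanning the magnitudes seen in embryonic metabolomes.

    A ~10-fold riser (glycerol-3-phosphate-like), a 98% late drop
    (kynurenine-like), a ~100-fold riser (uric-acid-like), an early
    10-fold dip with recovery (β-alanine-like) and a flat control.
    """
    return [
        TrajectorySpec("g3p_like", "fold_rise", 10.0),
        TrajectorySpec("kynurenine_like", "fold_drop", 0.02),
        TrajectorySpec("uric_acid_like", "fold_rise", 100.0),
        TrajectorySpec("beta_alanine_like", "early_drop_late_rise", 0.1),
        TrajectorySpec("flat_control", "flat", 1.0),
    ]


@dataclass(frozen=True)
class MetabolomeSimSpec:
    """Parameters of the simulated GC-MS peak-area time course."""

    trajectories: list[TrajectorySpec] = field(default_factory=example_trajectories)
    replicates: int = 7
    n_timepoints: int = 12
    noise_sd: float = 0.2            # lognormal sigma on each peak area
    standard_drift_sd: float = 0.3   # lognormal sigma of the per-sample injection factor
    base_area: float = 1e5
    standard_area: float = 1e4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need ≥2 replicates per timepoint")
        if self.n_timepoints < 2:
            raise ValueError("need ≥2 timepoints")
        if self.noise_sd < 0 or self.standard_drift_sd < 0:
            raise ValueError("noise sds must be ≥ 0")


def generate_metabolome(
    spec: MetabolomeSimSpec,
) -> tuple[MetaboliteTimecourse, SyntheticTruth]:
    """Simulate replicated peak-area samples from planted trajectories.

    Each sample's peak area is ``base_area · trajectory(t) · lognormal
    replicate noise · injection factor``; the internal-standard column
    carries ``standard_area · the same injection factor``, so dividing by
    it cancels the injection factor exactly.
    """
    rng = np.random.default_rng(spec.seed)
    T, R = spec.n_timepoints, spec.replicates
    labels = stage_labels_2h(T)
    truths = {tr.name: tr.trajectory(T) for tr in spec.trajectories}

    rows = []
    for ti, tp in enumerate(labels):
        for rep in range(R):
            inj = rng.lognormal(0.0, spec.standard_drift_sd) if spec.standard_drift_sd > 0 else 1.0
            row = {
                "sample_id": f"s_{tp}_r{rep}",
                "timepoint": tp,
                "replicate": rep,
                INTERNAL_STANDARD_COLUMN: spec.standard_area * inj,
            }
            for tr in spec.trajectories:
                noise = rng.lognormal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 1.0
                row[tr.name] = spec.base_area * truths[tr.name][ti] * noise * inj
            rows.append(row)
    tc = MetaboliteTimecourse(samples=pd.DataFrame(rows), timepoint_order=labels)
    truth = SyntheticTruth(true_trajectories=truths)
    return tc, truth


# ---------------------------------------------------------------------------
# nutrient stores

@dataclass(frozen=True)
class StoreSimSpec:
    """Simulated bulk store assay: linear trend with replicate noise."""

    analyte: str = "TAG"
    final_fold: float = 0.3
    n_timepoints: int = 4
    replicates: int = 6
    cv: float = 0.1
    baseline_level: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need ≥2 replicates")
        if self.final_fold < 0 or self.cv < 0 or self.baseline_level <= 0:
            raise ValueError("invalid store spec")


def generate_stores(spec: StoreSimSpec) -> tuple[StoreAssay, SyntheticTruth]:
    """Simulate a TAG/glycogen/protein-style assay with a linear trend."""
    rng = np.random.default_rng(spec.seed)
    labels = [f"{6 * i}-{6 * i + 2}h" for i in range(spec.n_timepoints)]
    traj = np.linspace(1.0, spec.final_fold, spec.n_timepoints)
    values = {}
    for t, lab in enumerate(labels):
        mean = spec.baseline_level * traj[t]
        vals = rng.normal(mean, spec.cv * mean, size=spec.replicates)
        values[lab] = np.clip(vals, 0.0, None)
    assay = StoreAssay(analyte=spec.analyte, values=values, baseline=labels[0])
    truth = SyntheticTruth(store_trajectories={spec.analyte: traj})
    return assay, truth
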