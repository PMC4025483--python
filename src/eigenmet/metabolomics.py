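"""Statistics for staged GC-MS metabolite tables and nutrient-store assays.

The workflow mirrors how targeted GC-MS time courses are analysed in
practice: integrated peak areas per sample are first divided by the
sample's spiked internal standard (removing per-injection instrument
variation), then expressed relative to the baseline timepoint (the
baseline median is fixed to 100), and finally each later timepoint is
compared with baseline by an unpaired Welch t-test.  Bulk nutrient-store
assays (triglyceride, glycogen, soluble protein) use the same
baseline-relative logic with replicate means, SEM and a pooled-variance
Student t-test.

Peak areas below detection are *missing*, not zero: they are excluded
from medians, quartiles and tests, while a measured zero is kept as a
zero.  All tests are two-sided and unpaired; no multiple-testing
correction is applied by default (a Benjamini–Hochberg column is
available behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaboliteTimecourse",
    "StoreAssay",
    "normalize_to_standard",
    "relative_to_baseline",
    "welch_test",
    "summarize",
    "ratio_series",
    "analyze_stores",
    "read_timecourse",
    "read_stores",
]

logger = logging.getLogger(__name__)

INTERNAL_STANDARD_COLUMN = "internal_standard"
_META_COLUMNS = ("sample_id", "timepoint", "replicate", INTERNAL_STANDARD_COLUMN)


@dataclass(frozen=True)
class MetaboliteTimecourse:
    """Replicated per-sample metabolite peak areas over ordered timepoints.

    ``samples`` is a wide table with one row per sample and columns
    ``sample_id``, ``timepoint``, ``replicate``, ``internal_standard``
    plus one column per metabolite.  Missing peak areas are NaN and stay
    distinct from measured zeros throughout.
    """

    samples: pd.DataFrame = field(repr=False)
    timepoint_order: list[str]
    normalized: bool = False
    baseline_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.samples.reset_index(drop=True)
        object.__setattr__(self, "samples", df)
        missing = [c for c in _META_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample table lacks required columns {missing}")
        unknown = set(df["timepoint"]) - set(self.timepoint_order)
        if unknown:
            raise ValueError(
                f"timepoint labels {sorted(unknown)} not in timepoint_order"
            )
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample IDs")

    @property
    def metabolite_names(self) -> list[str]:
        return [c for c in self.samples.columns if c not in _META_COLUMNS]

    def values_at(self, metabolite: str, timepoint: str) -> np.ndarray:
        """Non-missing values of one metabolite at one timepoint."""
        rows = self.samples[self.samples["timepoint"] == timepoint]
        return rows[metabolite].dropna().to_numpy(dtype=float)


@dataclass(frozen=True)
class StoreAssay:
    """Bulk nutrient-store measurements (one analyte, replicated bins).

    ``values`` maps each timepoint label to its replicate measurements;
    typically n = 6 pooled-embryo samples per bin.
    """

    analyte: str
    values: dict[str, np.ndarray]
    baseline: str

    def __post_init__(self) -> None:
        vals = {str(t): np.asarray(v, dtype=float) for t, v in self.values.items()}
        object.__setattr__(self, "values", vals)
        if self.baseline not in vals:
            raise ValueError(f"baseline {self.baseline!r} not among timepoints")
        for t, v in vals.items():
            if len(v) < 2:
                raise ValueError(f"timepoint {t!r} has {len(v)} replicates; need ≥2")
            if np.any(v < 0) or not np.all(np.isfinite(v)):
                raise ValueError(f"timepoint {t!r} has negative or non-finite values")


def normalize_to_standard(tc: MetaboliteTimecourse) -> MetaboliteTimecourse:
    """Divide every peak area by its sample's internal-standard area.

    Samples whose internal standard is missing or ≤ 0 indicate a failed
    injection and are excluded with a warning; downstream replicate
    counts shrink accordingly.  Missing peak areas remain missing.
    """
    df = tc.samples.copy()
    std = df[INTERNAL_STANDARD_COLUMN]
    bad = std.isna() | (std <= 0)
    if bad.any():
        for sid in df.loc[bad, "sample_id"]:
            logger.warning(
                "sample %s excluded: internal standard missing or ≤ 0", sid
            )
        df = df[~bad].reset_index(drop=True)
    if df.empty:
        raise ValueError("no samples left after internal-standard filtering")
    mets = tc.metabolite_names
    df[mets] = df[mets].div(df[INTERNAL_STANDARD_COLUMN], axis=0)
    df[INTERNAL_STANDARD_COLUMN] = 1.0
    return replace(tc, samples=df, normalized=True)


def relative_to_baseline(
    tc: MetaboliteTimecourse,
    baseline: str,
    scale: float = 100.0,
    statistic: str = "median",
) -> MetaboliteTimecourse:
    """Rescale each metabolite so its baseline statistic equals ``scale``.

    Every value is multiplied by ``scale / baseline_statistic``; with the
    default median statistic and scale 100, the baseline median of the
    output is exactly 100 for every metabolite detectable at baseline.

    A metabolite whose baseline statistic is 0 (or with no baseline
    measurement) cannot be expressed as a baseline fold change; its
    values are left as-is and it is flagged ``"undetectable at baseline"``
    in ``baseline_flags``.
    """
    if baseline not in tc.timepoint_order:
        raise ValueError(f"baseline {baseline!r} not in timepoint_order")
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    stat_fn = np.median if statistic == "median" else np.mean
    df = tc.samples.copy()
    flags = dict(tc.baseline_flags)
    for met in tc.metabolite_names:
        base_vals = tc.values_at(met, baseline)
        base_stat = float(stat_fn(base_vals)) if len(base_vals) else 0.0
        if base_stat <= 0:
            flags[met] = "undetectable at baseline"
            continue
        df[met] = df[met] * (scale / base_stat)
    return replace(tc, samples=df, baseline_flags=flags)


def welch_test(
    baseline: np.ndarray, other: np.ndarray
) -> tuple[float, float, float]:
    """Unpaired two-sample t-test with the Welch correction.

    Returns ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom and
    a two-sided p-value.  Degenerate cases: two zero-variance groups with
    equal means give ``(0, nan, 1)`` by convention; zero-variance groups
    with different means are flagged as an error (no finite statistic
    exists).
    """
    a = np.asarray(baseline, dtype=float)
    b = np.asarray(other, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs ≥2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float("nan"), 1.0
        raise ValueError(
            "both groups have zero variance but different means; "
            "the Welch statistic is undefined"
        )
    res = stats.ttest_ind(b, a, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def summarize(
    tc: MetaboliteTimecourse,
    baseline: str,
    alpha: float = 0.01,
    fdr: bool = False,
) -> pd.DataFrame:
    """Box-plot summaries and baseline comparisons per metabolite × bin.

    One row per metabolite × timepoint with replicate count, five-number
    summary (min, q1, median, q3, max) on the current scale, the Welch
    p-value against the baseline bin, and a significance flag at
    ``alpha``.  The baseline row itself is never flagged (self-comparison
    is skipped), and bins with fewer than 2 replicates get no p-value but
    are flagged ``"n<2"``.  With ``fdr=True`` a Benjamini–Hochberg
    adjusted column ``q_value`` is added and the flag uses it instead.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rows = []
    for met in tc.metabolite_names:
        base_vals = tc.values_at(met, baseline)
        for tp in tc.timepoint_order:
            vals = tc.values_at(met, tp)
            n = len(vals)
            rec: dict = {
                "metabolite": met,
                "timepoint": tp,
                "n": n,
                "median": np.nan,
                "q1": np.nan,
                "q3": np.nan,
                "min": np.nan,
                "max": np.nan,
                "p_value": np.nan,
                "significant": False,
                "flag": tc.baseline_flags.get(met, ""),
            }
            if n:
                rec.update(
                    median=float(np.median(vals)),
                    q1=float(np.percentile(vals, 25)),
                    q3=float(np.percentile(vals, 75)),
                    min=float(vals.min()),
                    max=float(vals.max()),
                )
            if tp != baseline and n >= 2 and len(base_vals) >= 2:
                try:
                    _, _, p = welch_test(base_vals, vals)
                    rec["p_value"] = p
                    rec["significant"] = bool(p < alpha)
                except ValueError:
                    rec["flag"] = (rec["flag"] + "; " if rec["flag"] else "") + "degenerate"
            elif tp != baseline and n < 2:
                rec["flag"] = (rec["flag"] + "; " if rec["flag"] else "") + "n<2"
            rows.append(rec)
    out = pd.DataFrame(rows)
    if fdr:
        mask = out["p_value"].notna()
        q = np.full(len(out), np.nan)
        if mask.any():
            q[mask.to_numpy()] = _benjamini_hochberg(out.loc[mask, "p_value"].to_numpy())
        out["q_value"] = q
        out["significant"] = out["q_value"].notna() & (out["q_value"] < alpha)
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def ratio_series(
    tc: MetaboliteTimecourse, numerator: str, denominator: str
) -> pd.DataFrame:
    """Within-sample ratio of two metabolites across the time course.

    A sample contributes a ratio only when both metabolites were measured
    and the denominator is positive; other samples are dropped with a
    warning.  Useful for redox-coupled pairs such as lactate/pyruvate,
    whose ratio tracks the cytosolic NADH/NAD⁺ balance.
    """
    for met in (numerator, denominator):
        if met not in tc.metabolite_names:
            raise ValueError(f"metabolite {met!r} not in table")
    df = tc.samples
    num, den = df[numerator], df[denominator]
    ok = num.notna() & den.notna() & (den > 0)
    dropped = (~ok).sum()
    if dropped:
        logger.warning(
            "%d samples lacked %s or had nonpositive %s and were excluded",
            dropped, numerator, denominator,
        )
    if not ok.any():
        raise ValueError(
            f"no samples have both {numerator!r} and positive {denominator!r}"
        )
    out = df.loc[ok, ["sample_id", "timepoint", "replicate"]].copy()
    out["ratio"] = (num / den)[ok]
    return out.reset_index(drop=True)


def analyze_stores(
    assay: StoreAssay, alpha: float = 0.05, scale: float = 1.0
) -> pd.DataFrame:
    """Baseline-relative means, SEM and Student t-tests for a store assay.

    Replicate values at every timepoint are divided by the baseline mean
    (so the normalised baseline mean equals ``scale``, 1.0 by default),
    and each later bin is compared with baseline by a pooled-variance
    two-sample t-test.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    base = assay.values[assay.baseline]
    base_mean = float(base.mean())
    if base_mean == 0:
        raise ValueError("baseline mean is zero; cannot normalise")
    factor = scale / base_mean
    rows = []
    for tp, vals in assay.values.items():
        norm = vals * factor
        n = len(norm)
        rec = {
            "analyte": assay.analyte,
            "timepoint": tp,
            "n": n,
            "mean": float(norm.mean()),
            "sem": float(norm.std(ddof=1) / np.sqrt(n)),
            "p_value": np.nan,
            "significant": False,
        }
        if tp != assay.baseline:
            res = stats.ttest_ind(vals, base, equal_var=True)
            rec["p_value"] = float(res.pvalue)
            rec["significant"] = bool(res.pvalue < alpha)
        rows.append(rec)
    return pd.DataFrame(rows)


def read_timecourse(
    path, timepoint_order: list[str] | None = None
) -> MetaboliteTimecourse:
    """Read a metabolite sample table (TSV; CSV by extension).

    Accepts the wide layout (one row per sample; ``sample_id``,
    ``timepoint``, ``replicate``, ``internal_standard`` + metabolite
    columns) or the long layout (``sample_id``, ``timepoint``,
    ``replicate``, ``metabolite``, ``peak_area``, with the internal
    standard as a metabolite named ``internal_standard``), which is
    pivoted to wide.  Timepoint order defaults to first appearance.
    """
    from pathlib import Path

    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if "metabolite" in df.columns and "peak_area" in df.columns:
        wide = df.pivot_table(
            index=["sample_id", "timepoint", "replicate"],
            columns="metabolite",
            values="peak_area",
            aggfunc="first",
        ).reset_index()
        wide.columns.name = None
        df = wide
    if INTERNAL_STANDARD_COLUMN not in df.columns:
        raise ValueError(f"{path}: no {INTERNAL_STANDARD_COLUMN!r} column")
    if timepoint_order is None:
        timepoint_order = list(dict.fromkeys(df["timepoint"].astype(str)))
    df["timepoint"] = df["timepoint"].astype(str)
    return MetaboliteTimecourse(samples=df, timepoint_order=timepoint_order)


def read_stores(path, baseline: str | None = None) -> list[StoreAssay]:
    """Read store-assay tables: TSV with analyte, timepoint, replicate, value."""
    from pathlib import Path

    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    need = {"analyte", "timepoint", "replicate", "value"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    df["timepoint"] = df["timepoint"].astype(str)
    assays = []
    for analyte, grp in df.groupby("analyte", sort=False):
        order = list(dict.fromkeys(grp["timepoint"]))
        vals = {t: g["value"].to_numpy(dtype=float) for t, g in grp.groupby("timepoint", sort=False)}
        assays.append(
            StoreAssay(analyte=str(analyte), values=vals, baseline=baseline or order[0])
        )
    return assays
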