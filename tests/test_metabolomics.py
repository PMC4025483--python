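"""Metabolite time-course statistics: normalization, tests, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import eigenmet as em
from eigenmet import (
    MetaboliteTimecourse,
    StoreAssay,
    analyze_stores,
    normalize_to_standard,
    ratio_series,
    relative_to_baseline,
    summarize,
    welch_test,
)
from eigenmet.metabolomics import read_stores, read_timecourse


def make_tc(rows, order=("0-2h", "2-4h", "4-6h")):
    return MetaboliteTimecourse(samples=pd.DataFrame(rows), timepoint_order=list(order))


def simple_tc(standard=1.0):
    rows = []
    for ti, tp in enumerate(["0-2h", "2-4h", "4-6h"]):
        for rep, base in enumerate([2.0, 4.0, 6.0]):
            rows.append(
                {
                    "sample_id": f"s{ti}{rep}",
                    "timepoint": tp,
                    "replicate": rep,
                    "internal_standard": standard,
                    "metA": base * (ti + 1),
                    "metB": base,
                }
            )
    return make_tc(rows)


def welch_oracle(a, b):
    """Hand-written Welch formulas, independent of the implementation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (b.mean() - a.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


class TestNormalize:
    def test_unit_standard_is_identity(self):
        tc = simple_tc(standard=1.0)
        out = normalize_to_standard(tc)
        pd.testing.assert_frame_equal(out.samples, tc.samples)

    def test_division_by_standard(self):
        rows = [
            {"sample_id": "a", "timepoint": "0-2h", "replicate": 0,
             "internal_standard": 2.0, "met": 50.0},
            {"sample_id": "b", "timepoint": "0-2h", "replicate": 1,
             "internal_standard": 5.0, "met": 50.0},
        ]
        out = normalize_to_standard(make_tc(rows, order=["0-2h"]))
        np.testing.assert_allclose(out.samples["met"], [25.0, 10.0])

    def test_zero_standard_sample_dropped(self, caplog):
        rows = [
            {"sample_id": f"s{r}", "timepoint": "0-2h", "replicate": r,
             "internal_standard": std, "met": 1.0}
            for r, std in enumerate([1.0, 1.0, 0.0])
        ]
        with caplog.at_level("WARNING"):
            out = normalize_to_standard(make_tc(rows, order=["0-2h"]))
        assert len(out.samples) == 2
        assert "excluded" in caplog.text

    def test_missing_stays_missing(self):
        rows = [
            {"sample_id": "a", "timepoint": "0-2h", "replicate": 0,
             "internal_standard": 2.0, "met": np.nan},
        ]
        out = normalize_to_standard(make_tc(rows, order=["0-2h"]))
        assert np.isnan(out.samples["met"]).all()


class TestBaselineRelative:
    def test_forced_arithmetic(self):
        rows = [
            {"sample_id": f"b{r}", "timepoint": "0-2h", "replicate": r,
             "internal_standard": 1.0, "met": v}
            for r, v in enumerate([2.0, 4.0, 6.0])
        ] + [
            {"sample_id": "x", "timepoint": "2-4h", "replicate": 0,
             "internal_standard": 1.0, "met": 8.0}
        ]
        out = relative_to_baseline(make_tc(rows, order=["0-2h", "2-4h"]), "0-2h")
        assert out.values_at("met", "2-4h")[0] == pytest.approx(200.0)

    def test_baseline_median_fixed_point(self, metab_bundle):
        _, _, _, scaled = metab_bundle
        for met in scaled.metabolite_names:
            if met not in scaled.baseline_flags:
                assert np.median(scaled.values_at(met, "0-2h")) == pytest.approx(100.0)

    def test_baseline_zero_flagged_not_rescaled(self):
        rows = [
            {"sample_id": f"s_{tp}_{r}", "timepoint": tp, "replicate": r,
             "internal_standard": 1.0, "met": 0.0 if tp == "0-2h" else 5.0}
            for tp in ["0-2h", "2-4h"] for r in range(3)
        ]
        out = relative_to_baseline(make_tc(rows, order=["0-2h", "2-4h"]), "0-2h")
        assert out.baseline_flags["met"] == "undetectable at baseline"
        np.testing.assert_allclose(out.values_at("met", "2-4h"), 5.0)

    def test_unknown_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            relative_to_baseline(simple_tc(), "99-101h")


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_frozen_hand_oracle(self):
        # (1,2,3) vs (2,3,4): t = √(3/2), df = 4, p = 0.287864…
        t, df, p = welch_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert t == pytest.approx(np.sqrt(1.5), abs=1e-12)
        assert df == pytest.approx(4.0, abs=1e-12)
        assert p == pytest.approx(0.28786413472669053, abs=1e-12)

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            na, nb = rng.integers(2, 9, size=2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=nb)
            got = welch_test(a, b)
            want = welch_oracle(a, b)
            np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_degenerate_zero_variance(self):
        assert welch_test([2.0, 2.0], [2.0, 2.0]) == (0.0, pytest.approx(np.nan, nan_ok=True), 1.0)
        with pytest.raises(ValueError, match="zero variance"):
            welch_test([2.0, 2.0], [3.0, 3.0])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="≥2"):
            welch_test([1.0], [1.0, 2.0])

    def test_type_one_error_near_nominal(self):
        """n=6 vs n=6 null draws: rejection rate at α=0.01 stays within
        (0.005, 0.018) over 10,000 simulations."""
        rng = np.random.default_rng(2024)
        a = rng.normal(size=(10000, 6))
        b = rng.normal(size=(10000, 6))
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
        # cross-check the vectorized run against our scalar implementation
        for i in range(50):
            _, _, p = welch_test(a[i], b[i])
            assert p == pytest.approx(res.pvalue[i], rel=1e-12)
        rate = float(np.mean(res.pvalue < 0.01))
        assert 0.005 < rate < 0.018


class TestSummarize:
    def test_baseline_row_never_significant(self, metab_bundle):
        _, _, _, scaled = metab_bundle
        summ = summarize(scaled, "0-2h")
        base = summ[summ["timepoint"] == "0-2h"]
        assert not base["significant"].any()
        assert base["p_value"].isna().all()

    def test_box_statistics_ordered(self, metab_bundle):
        _, _, _, scaled = metab_bundle
        summ = summarize(scaled, "0-2h").dropna(subset=["median"])
        assert (summ["min"] <= summ["q1"]).all()
        assert (summ["q1"] <= summ["median"] + 1e-12).all()
        assert (summ["median"] <= summ["q3"] + 1e-12).all()
        assert (summ["q3"] <= summ["max"]).all()

    def test_planted_rise_flagged_significant(self, metab_bundle):
        _, _, _, scaled = metab_bundle
        summ = summarize(scaled, "0-2h")
        final = summ[(summ.metabolite == "g3p_like") & (summ.timepoint == "22-24h")]
        assert final["significant"].item()

    def test_small_n_flagged_without_p(self):
        rows = [
            {"sample_id": f"b{r}", "timepoint": "0-2h", "replicate": r,
             "internal_standard": 1.0, "met": float(r + 1)}
            for r in range(3)
        ] + [
            {"sample_id": "x", "timepoint": "2-4h", "replicate": 0,
             "internal_standard": 1.0, "met": 9.0}
        ]
        summ = summarize(make_tc(rows, order=["0-2h", "2-4h"]), "0-2h")
        row = summ[summ["timepoint"] == "2-4h"].iloc[0]
        assert np.isnan(row["p_value"]) and "n<2" in row["flag"]

    def test_order_invariance(self, metab_bundle):
        _, _, _, scaled = metab_bundle
        shuffled = scaled.samples.sample(frac=1.0, random_state=1)
        tc2 = MetaboliteTimecourse(
            samples=shuffled, timepoint_order=scaled.timepoint_order,
            normalized=True, baseline_flags=scaled.baseline_flags,
        )
        a = summarize(scaled, "0-2h").reset_index(drop=True)
        b = summarize(tc2, "0-2h").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_fdr_column_available(self, metab_bundle):
        _, _, _, scaled = metab_bundle
        summ = summarize(scaled, "0-2h", fdr=True)
        assert "q_value" in summ.columns
        ok = summ.dropna(subset=["p_value", "q_value"])
        assert (ok["q_value"] >= ok["p_value"] - 1e-12).all()


class TestRatioSeries:
    def test_self_ratio_is_one(self, metab_bundle):
        _, _, _, scaled = metab_bundle
        out = ratio_series(scaled, "g3p_like", "g3p_like")
        np.testing.assert_allclose(out["ratio"], 1.0)

    def test_proportional_pair_constant(self):
        rng = np.random.default_rng(8)
        rows = []
        for ti, tp in enumerate(["0-2h", "2-4h", "4-6h"]):
            for rep in range(4):
                f = rng.lognormal(0, 0.4)
                rows.append(
                    {"sample_id": f"s{ti}{rep}", "timepoint": tp, "replicate": rep,
                     "internal_standard": 1.0, "lac": 3.0 * f * (ti + 1), "pyr": f * (ti + 1)}
                )
        out = ratio_series(make_tc(rows), "lac", "pyr")
        np.testing.assert_allclose(out["ratio"], 3.0)

    def test_zero_denominator_sample_excluded(self, caplog):
        rows = [
            {"sample_id": "a", "timepoint": "0-2h", "replicate": 0,
             "internal_standard": 1.0, "num": 1.0, "den": 2.0},
            {"sample_id": "b", "timepoint": "0-2h", "replicate": 1,
             "internal_standard": 1.0, "num": 1.0, "den": 0.0},
        ]
        with caplog.at_level("WARNING"):
            out = ratio_series(make_tc(rows, order=["0-2h"]), "num", "den")
        assert list(out["sample_id"]) == ["a"]
        assert "excluded" in caplog.text

    def test_no_overlap_rejected(self):
        rows = [
            {"sample_id": "a", "timepoint": "0-2h", "replicate": 0,
             "internal_standard": 1.0, "num": 1.0, "den": np.nan},
        ]
        with pytest.raises(ValueError, match="no samples"):
            ratio_series(make_tc(rows, order=["0-2h"]), "num", "den")


class TestStores:
    def test_baseline_mean_fixed_point(self):
        assay, _ = em.generate_stores(em.StoreSimSpec(seed=1))
        out = analyze_stores(assay)
        base = out[out["timepoint"] == assay.baseline]
        assert base["mean"].item() == pytest.approx(1.0)

    def test_planted_decline_flagged(self):
        assay, _ = em.generate_stores(em.StoreSimSpec(final_fold=0.3, seed=2))
        out = analyze_stores(assay, alpha=0.05)
        assert out.iloc[-1]["significant"]

    def test_identical_replicates_never_flagged(self):
        vals = {t: np.array([5.0, 6.0, 7.0]) for t in ["0-2h", "6-8h"]}
        assay = StoreAssay(analyte="glycogen", values=vals, baseline="0-2h")
        out = analyze_stores(assay)
        assert not out["significant"].any()

    def test_pooled_t_matches_scipy(self):
        assay, _ = em.generate_stores(em.StoreSimSpec(seed=3))
        out = analyze_stores(assay)
        base = assay.values[assay.baseline]
        tp = list(assay.values)[2]
        expect = stats.ttest_ind(assay.values[tp], base, equal_var=True).pvalue
        assert out[out["timepoint"] == tp]["p_value"].item() == pytest.approx(expect)

    def test_validation(self):
        with pytest.raises(ValueError, match="replicates"):
            StoreAssay("TAG", {"0-2h": np.array([1.0])}, "0-2h")
        with pytest.raises(ValueError, match="baseline"):
            StoreAssay("TAG", {"0-2h": np.array([1.0, 2.0])}, "9h")


class TestIO:
    def test_wide_and_long_round_trip(self, tmp_path, metab_bundle):
        _, tc, _, _ = metab_bundle
        wide = tmp_path / "wide.tsv"
        tc.samples.to_csv(wide, sep="\t", index=False)
        back = read_timecourse(wide, timepoint_order=tc.timepoint_order)
        pd.testing.assert_frame_equal(
            back.samples[tc.samples.columns], tc.samples, check_dtype=False
        )
        long = tc.samples.melt(
            id_vars=["sample_id", "timepoint", "replicate"],
            var_name="metabolite", value_name="peak_area",
        )
        lpath = tmp_path / "long.tsv"
        long.to_csv(lpath, sep="\t", index=False)
        back2 = read_timecourse(lpath, timepoint_order=tc.timepoint_order)
        for met in tc.metabolite_names:
            for tp in tc.timepoint_order:
                np.testing.assert_allclose(
                    np.sort(back2.values_at(met, tp)), np.sort(tc.values_at(met, tp))
                )

    def test_read_stores(self, tmp_path):
        path = tmp_path / "stores.tsv"
        rows = ["analyte\ttimepoint\treplicate\tvalue"]
        for an in ["TAG", "glycogen"]:
            for tp in ["0-2h", "6-8h"]:
                for r in range(3):
                    rows.append(f"{an}\t{tp}\t{r}\t{10 + r}")
        path.write_text("\n".join(rows) + "\n")
        assays = read_stores(path)
        assert [a.analyte for a in assays] == ["TAG", "glycogen"]
        assert assays[0].baseline == "0-2h"
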