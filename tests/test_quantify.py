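"""Channel normalization, capped ratios, replicate aggregation and
replicate correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hlaquant.quantify import (CAP_HEAVY_ONLY, CAP_LIGHT_ONLY,
                               aggregate_replicates, compute_ratios,
                               normalization_factors, normalize_channels,
                               quantify_table, replicate_correlation)


def table(rows):
    return pd.DataFrame(rows, columns=["peptide", "replicate",
                                       "intensity_L", "intensity_H"])


class TestNormalizeChannels:
    def test_factor_forced_by_definition(self):
        t = table([("a", "R1", 10.0, 5.0), ("b", "R1", 10.0, 5.0)])
        assert normalization_factors(t) == {"R1": 2.0}
        normed = normalize_channels(t)
        assert np.allclose(normed["intensity_H"], [10.0, 10.0])
        ratios = compute_ratios(normed, "peptide")
        assert np.allclose(ratios["ratio_hl"], 1.0)

    def test_balanced_table_unchanged(self):
        rng = np.random.default_rng(0)
        light = rng.uniform(1, 100, 50)
        t = table([(f"p{i}", "R1", light[i], light[i]) for i in range(50)])
        normed = normalize_channels(t)
        assert np.allclose(normed["intensity_H"], t["intensity_H"],
                           rtol=1e-12)

    def test_random_table_sums_match_after_normalization(self):
        rng = np.random.default_rng(42)
        t = table([(f"p{i}", "R1", rng.uniform(1, 1000), rng.uniform(1, 1000))
                   for i in range(100)])
        normed = normalize_channels(t)
        assert np.isclose(normed["intensity_H"].sum(),
                          normed["intensity_L"].sum(), rtol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        t = table([(f"p{i}", "R1", rng.uniform(1, 100), rng.uniform(1, 100))
                   for i in range(20)])
        once = normalize_channels(t)
        twice = normalize_channels(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_absent_channel_error_names_replicate(self):
        t = table([("a", "R2", 10.0, np.nan), ("b", "R2", 5.0, np.nan)])
        with pytest.raises(ValueError, match="R2"):
            normalize_channels(t)

    def test_median_method_centers_median_ratio(self):
        rng = np.random.default_rng(1)
        light = rng.uniform(10, 100, 31)
        ratios = 2.0 ** rng.normal(-0.5, 0.4, 31)
        t = table([(f"p{i}", "R1", light[i], light[i] * ratios[i])
                   for i in range(31)])
        f = normalization_factors(t, method="median")["R1"]
        normed = normalize_channels(t, {"R1": f})
        r = compute_ratios(normed, "peptide")
        assert np.isclose(np.median(r["ratio_hl"]), 1.0, rtol=1e-9)


class TestComputeRatios:
    def test_measured_ratio(self):
        # H=71 over L=100 -> 0.71, a 1.4-fold reduction
        t = table([("a", "R1", 100.0, 71.0)])
        r = compute_ratios(t, "peptide").iloc[0]
        assert np.isclose(r["ratio_hl"], 0.71)
        assert np.isclose(r["log2_ratio"], np.log2(0.71))
        assert r["capped"] == "none"

    def test_light_only_capped(self):
        t = table([("a", "R1", 100.0, np.nan)])
        r = compute_ratios(t, "peptide").iloc[0]
        assert r["ratio_hl"] == CAP_LIGHT_ONLY
        assert r["capped"] == "light_only"

    def test_heavy_only_capped(self):
        t = table([("a", "R1", np.nan, 64.0)])
        r = compute_ratios(t, "peptide").iloc[0]
        assert r["ratio_hl"] == CAP_HEAVY_ONLY
        assert r["capped"] == "heavy_only"

    def test_equal_channels_unity(self):
        r = compute_ratios(table([("a", "R1", 50.0, 50.0)]), "peptide").iloc[0]
        assert r["ratio_hl"] == 1.0
        assert r["log2_ratio"] == 0.0

    def test_both_absent_dropped(self):
        t = table([("a", "R1", np.nan, np.nan), ("b", "R1", 1.0, 2.0)])
        r = compute_ratios(t, "peptide")
        assert list(r["peptide"]) == ["b"]

    @given(st.lists(
        st.tuples(st.floats(1.0, 100.0), st.floats(1.0, 100.0),
                  st.sampled_from(["both", "light_only", "heavy_only"])),
        min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_capping_property_randomized(self, rows):
        """Ratios always lie in [0.01, 256]; capping iff one channel."""
        t = table([(f"p{i}", "R1",
                    light if kind != "heavy_only" else np.nan,
                    heavy if kind != "light_only" else np.nan)
                   for i, (light, heavy, kind) in enumerate(rows)])
        r = compute_ratios(t, "peptide")
        assert r["ratio_hl"].between(CAP_LIGHT_ONLY, CAP_HEAVY_ONLY).all()
        capped = r[r["capped"] != "none"]
        assert ((capped["ratio_hl"] == CAP_HEAVY_ONLY)
                | (capped["ratio_hl"] == CAP_LIGHT_ONLY)).all()
        for (_, _, kind), (_, row) in zip(rows, r.iterrows()):
            expected = {"both": "none", "light_only": "light_only",
                        "heavy_only": "heavy_only"}[kind]
            assert row["capped"] == expected


def rep_ratios(log2s, capped=None):
    capped = capped or ["none"] * len(log2s)
    return pd.DataFrame({
        "peptide": ["p"] * len(log2s),
        "replicate": [f"R{i}" for i in range(len(log2s))],
        "ratio_hl": [2.0 ** x for x in log2s],
        "log2_ratio": log2s,
        "capped": capped,
    })


class TestAggregateReplicates:
    def test_zero_variance_no_pvalue(self):
        q = aggregate_replicates(rep_ratios([-1.0, -1.0, -1.0]), "peptide")
        assert q.iloc[0]["log2_ratio"] == -1.0
        assert np.isnan(q.iloc[0]["p_value"])

    def test_pvalue_matches_closed_form_t_tail(self):
        # independent oracle: t = mean/(sd/sqrt(3)), p = 2 P(T_2 > |t|)
        vals = np.array([0.2, -0.1, 0.5])
        q = aggregate_replicates(rep_ratios(list(vals)), "peptide")
        t_stat = vals.mean() / (vals.std(ddof=1) / np.sqrt(3))
        expected = 2 * stats.t.sf(abs(t_stat), df=2)
        assert np.isclose(q.iloc[0]["p_value"], expected, rtol=1e-9)

    def test_single_replicate(self):
        q = aggregate_replicates(rep_ratios([0.7]), "peptide")
        assert q.iloc[0]["log2_ratio"] == 0.7
        assert np.isnan(q.iloc[0]["p_value"])

    def test_median_excludes_capped_replicates(self):
        df = rep_ratios([np.log2(256), 0.5, 0.3],
                        capped=["heavy_only", "none", "none"])
        q = aggregate_replicates(df, "peptide")
        assert np.isclose(q.iloc[0]["log2_ratio"], 0.4)
        assert q.iloc[0]["capped"] == "none"
        assert q.iloc[0]["n_reps"] == 3

    def test_all_heavy_only_gives_capped_summary(self):
        df = rep_ratios([8.0, 8.0], capped=["heavy_only", "heavy_only"])
        q = aggregate_replicates(df, "peptide")
        assert q.iloc[0]["ratio_hl"] == CAP_HEAVY_ONLY
        assert q.iloc[0]["capped"] == "heavy_only"

    def test_permutation_invariant(self):
        vals = [0.3, -0.2, 0.9]
        a = aggregate_replicates(rep_ratios(vals), "peptide")
        b = aggregate_replicates(rep_ratios(vals[::-1]), "peptide")
        assert a.iloc[0]["log2_ratio"] == b.iloc[0]["log2_ratio"]
        assert np.isclose(a.iloc[0]["p_value"], b.iloc[0]["p_value"])

    def test_empty_input(self):
        q = aggregate_replicates(rep_ratios([]), "peptide")
        assert len(q) == 0


class TestReplicateCorrelation:
    def _make(self, log2_a, log2_b, reps=("R1", "R2")):
        rows = []
        for i, (a, b) in enumerate(zip(log2_a, log2_b)):
            rows.append({"peptide": f"p{i}", "replicate": reps[0],
                         "ratio_hl": 2.0 ** a, "log2_ratio": a, "capped": "none"})
            rows.append({"peptide": f"p{i}", "replicate": reps[1],
                         "ratio_hl": 2.0 ** b, "log2_ratio": b, "capped": "none"})
        return pd.DataFrame(rows)

    def test_duplicated_replicate_perfect_correlation(self):
        x = [0.1, -0.5, 0.9, 0.2]
        mat = replicate_correlation(self._make(x, x), "peptide")
        assert np.isclose(mat.loc["R1", "R2"], 1.0)
        assert np.allclose(np.diag(mat), 1.0)

    def test_negated_replicate_anticorrelated(self):
        x = [0.1, -0.5, 0.9, 0.2]
        mat = replicate_correlation(self._make(x, [-v for v in x]), "peptide")
        assert np.isclose(mat.loc["R1", "R2"], -1.0)

    def test_too_few_shared_rows_absent(self):
        mat = replicate_correlation(self._make([0.1, 0.2], [0.3, 0.1]),
                                    "peptide")
        assert np.isnan(mat.loc["R1", "R2"])

    def test_synthetic_replicates_highly_correlated(self, pipeline_run):
        _, summary = pipeline_run
        assert summary["peptidome"]["min_replicate_correlation"] > 0.8


def test_quantify_table_end_to_end_sign_recovery(experiment):
    """With a planted global downshift the median summary log2 is negative."""
    quant = quantify_table(experiment.peptide_table, "peptide")
    measured = quant[quant["capped"] == "none"]
    assert np.median(measured["log2_ratio"]) < 0
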