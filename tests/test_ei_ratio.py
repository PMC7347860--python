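import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tei.core_io import DEFAULT_PANELS, ExpressionTable, GenePanel, ValidationError
from tei.ei_ratio import (
    compare_groups,
    compute_tei,
    fit_trend,
    group_summary,
    prepost_correlations,
    regress_totals,
    transporter_ratios,
)
from tei.synthetic_data import default_dev_config, gen_developmental

AMPAR = DEFAULT_PANELS["AMPAR"]
GABAAR_SMALL = GenePanel("GABAAR", ("GABRA1", "GABRB2"))


def _linear_table(adict, meta=None):
    values = pd.DataFrame(adict)
    values.index = [f"s{i}" for i in range(len(values))]
    if meta is not None:
        meta = pd.DataFrame(meta, index=values.index)
    return ExpressionTable(values, "linear", None, meta)


class TestComputeTei:
    def test_equal_sums_give_ratio_1(self):
        t = _linear_table({"GRIA1": [2.0], "GRIA2": [2.0],
                           "GABRA1": [3.0], "GABRB2": [1.0]})
        rec = compute_tei(t, GenePanel("A", ("GRIA1", "GRIA2")), GABAAR_SMALL)
        assert rec["tei"].iloc[0] == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        base = {g: rng.uniform(1, 10, 5) for g in
                ("GRIA1", "GRIA2", "GABRA1", "GABRB2")}
        t1 = _linear_table(base)
        t2 = _linear_table({g: v * 11.0 for g, v in base.items()})
        r1 = compute_tei(t1, GenePanel("A", ("GRIA1", "GRIA2")), GABAAR_SMALL)
        r2 = compute_tei(t2, GenePanel("A", ("GRIA1", "GRIA2")), GABAAR_SMALL)
        np.testing.assert_allclose(r1["tei"], r2["tei"], rtol=1e-12)

    def test_panel_swap_inverts_ratio(self):
        rng = np.random.default_rng(1)
        base = {g: rng.uniform(1, 10, 5) for g in
                ("GRIA1", "GRIA2", "GABRA1", "GABRB2")}
        t = _linear_table(base)
        a, g = GenePanel("A", ("GRIA1", "GRIA2")), GABAAR_SMALL
        fwd = compute_tei(t, a, g)["tei"]
        rev = compute_tei(t, g, a)["tei"]
        np.testing.assert_allclose(fwd * rev, 1.0, rtol=1e-12)

    def test_zero_denominator_missing_with_warning(self, caplog):
        t = _linear_table({"GRIA1": [2.0], "GABRA1": [0.0], "GABRB2": [0.0]})
        rec = compute_tei(t, GenePanel("A", ("GRIA1",)), GABAAR_SMALL)
        assert np.isnan(rec["tei"].iloc[0])
        assert any("tE/I missing" in r.message for r in caplog.records)

    def test_log2_table_exponentiated_before_summing(self):
        vals = pd.DataFrame({"GRIA1": [3.0], "GABRA1": [1.0], "GABRB2": [1.0]},
                            index=["s0"])
        t = ExpressionTable(vals, "log2")
        rec = compute_tei(t, GenePanel("A", ("GRIA1",)), GABAAR_SMALL)
        assert rec["tei"].iloc[0] == pytest.approx(8.0 / 4.0)

    def test_group_summary_reports_n_mean_sd_sem(self, single_cell):
        table, meta, truth = single_cell
        rec = compute_tei(table, group_by="cell_type", policy="subset")
        summ = group_summary(rec, "cell_type")
        assert {"n", "mean", "sd", "sem"} <= set(summ.columns)
        np.testing.assert_allclose(summ["sem"], summ["sd"] / np.sqrt(summ["n"]))

    def test_recovers_configured_cell_type_means(self, single_cell):
        """Per-type mean tE/I lands within 3 SEM of each configured mean
        (0.66 for CCKC basket cells up to 10 for Martinotti cells)."""
        table, meta, truth = single_cell
        rec = compute_tei(table, group_by="cell_type", policy="subset")
        summ = group_summary(rec, "cell_type").set_index("cell_type")
        for name, mu in truth.group_tei.items():
            row = summ.loc[name]
            assert abs(row["mean"] - mu) < 3 * row["sem"], name


class TestRegressTotals:
    def test_exact_collinear_sums(self):
        g = np.linspace(10, 100, 20)
        rec = pd.DataFrame({"sum_gabaar": g, "sum_ampar": 2.5 * g + 3.0,
                            "tei": (2.5 * g + 3.0) / g})
        out = regress_totals(rec)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["slope"].iloc[0] == pytest.approx(2.5)
        assert out["intercept"].iloc[0] == pytest.approx(3.0)

    def test_recovers_per_group_slopes(self):
        """Planted per-structure slopes (0.5, 1.0, 2.0) are recovered
        within 10% at n=200 per group."""
        rng = np.random.default_rng(2)
        frames = []
        for name, slope in (("a", 0.5), ("b", 1.0), ("c", 2.0)):
            g = rng.uniform(50, 150, 200)
            a = slope * g + rng.normal(0, 3.0, 200)
            frames.append(pd.DataFrame({"sum_gabaar": g, "sum_ampar": a,
                                        "tei": a / g, "structure": name}))
        out = regress_totals(pd.concat(frames, ignore_index=True),
                             group_by="structure").set_index("group")
        for name, slope in (("a", 0.5), ("b", 1.0), ("c", 2.0)):
            assert out.loc[name, "slope"] == pytest.approx(slope, rel=0.10)
            assert out.loc[name, "p"] < 0.001

    def test_null_r_small_and_p_uniform(self):
        """With independent sums the correlation is near zero and p-values
        are uniform over seeded replicates."""
        rng = np.random.default_rng(3)
        pvals, rs = [], []
        for _ in range(200):
            g = rng.uniform(50, 150, 30)
            a = rng.uniform(50, 150, 30)
            out = regress_totals(pd.DataFrame(
                {"sum_gabaar": g, "sum_ampar": a, "tei": a / g}))
            pvals.append(out["p"].iloc[0])
            rs.append(out["r"].iloc[0])
        assert abs(np.mean(rs)) < 0.05
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_degenerate_variance_missing(self, caplog):
        rec = pd.DataFrame({"sum_gabaar": [5.0, 5.0, 5.0],
                            "sum_ampar": [1.0, 2.0, 3.0],
                            "tei": [0.2, 0.4, 0.6]})
        out = regress_totals(rec)
        assert np.isnan(out["slope"].iloc[0])
        assert any("degenerate" in r.message for r in caplog.records)


def welch_oracle(a, b):
    """Textbook Welch t with Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def tukey_kramer_oracle(groups):
    """Studentized-range pairwise p-values at unequal n."""
    names = list(groups)
    k = len(names)
    ns = {g: len(v) for g, v in groups.items()}
    df = sum(ns.values()) - k
    mse = sum(((np.asarray(v) - np.mean(v)) ** 2).sum()
              for v in groups.values()) / df
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = np.sqrt(mse / 2 * (1 / ns[a] + 1 / ns[b]))
            q = abs(np.mean(groups[a]) - np.mean(groups[b])) / se
            out[(a, b)] = stats.studentized_range.sf(q, k, df)
    return out


class TestCompareGroups:
    def _records(self, groups):
        rows = [{"tei": x, "cell_type": g} for g, xs in groups.items()
                for x in xs]
        return pd.DataFrame(rows)

    def test_identical_groups_t0_p1(self):
        rec = self._records({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        out = compare_groups(rec, "cell_type", "welch_two_sample")
        assert out["t"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_welch_matches_formula_oracle(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 2.0, 7)
        out = compare_groups(self._records({"a": a, "b": b}),
                             "cell_type", "welch_two_sample")
        t, df, p = welch_oracle(a, b)
        assert out["t"].iloc[0] == pytest.approx(t, abs=1e-10)
        assert out["df"].iloc[0] == pytest.approx(df, abs=1e-10)
        assert out["p"].iloc[0] == pytest.approx(p, abs=1e-10)

    def test_tukey_kramer_matches_oracle(self):
        rng = np.random.default_rng(5)
        groups = {"a": rng.normal(0, 1, 8), "b": rng.normal(1, 1, 5),
                  "c": rng.normal(2, 1, 11)}
        out = compare_groups(self._records(groups), "cell_type",
                             "anova_tukey_kramer")
        oracle = tukey_kramer_oracle(groups)
        for _, row in out.iterrows():
            key = (row["group_a"], row["group_b"])
            key = key if key in oracle else key[::-1]
            assert row["p"] == pytest.approx(oracle[key], abs=1e-8)

    def test_welch_type_i_error_calibrated(self):
        """Null rejection rate at alpha=0.05 sits in [0.035, 0.065]."""
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 500
        for _ in range(reps):
            a, b = rng.normal(0, 1, 15), rng.normal(0, 1.5, 12)
            _, _, p = welch_oracle(a, b)
            res = stats.ttest_ind(a, b, equal_var=False)
            rejections += res.pvalue < 0.05
        assert 0.025 <= rejections / reps <= 0.075

    def test_outlier_group_flagged_against_all(self, single_cell):
        """The tenfold-higher Martinotti-like group differs from every
        other type at p < 0.0001 under Tukey-Kramer."""
        table, meta, truth = single_cell
        from tei.ei_ratio import compute_tei
        rec = compute_tei(table, group_by="cell_type", policy="subset")
        out = compare_groups(rec, "cell_type", "anova_tukey_kramer")
        mnc = out[(out.group_a == "MNC") | (out.group_b == "MNC")]
        assert len(mnc) == 6
        assert (mnc["p"] < 0.0001).all()
        assert out.attrs["anova_p"] < 1e-10

    def test_single_unit_group_rejected(self):
        rec = self._records({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(ValidationError, match="a"):
            compare_groups(rec, "cell_type", "welch_two_sample")


class TestTransporters:
    def test_equal_levels_give_ratio_1(self):
        t = _linear_table({"SLC12A5": [4.0], "SLC12A2": [4.0],
                           "SLC12A1": [1.0]})
        out = transporter_ratios(t)
        assert out["kcc2_nkcc1"].iloc[0] == pytest.approx(1.0)

    def test_missing_gene_gives_missing_ratio(self):
        t = _linear_table({"SLC12A5": [4.0]})
        out = transporter_ratios(t)
        assert np.isnan(out["kcc2_nkcc1"].iloc[0])

    def test_noise_free_ratio_matches_configured_curves(self):
        cfg = default_dev_config(seed=0)
        cfg.noise_sd = 0.0
        table, meta, truth = gen_developmental(cfg)
        out = transporter_ratios(table)
        expected = np.interp(meta["age"], truth.age_grid, truth.kcc2_nkcc1)
        np.testing.assert_allclose(out["kcc2_nkcc1"], expected, rtol=1e-9)

    def test_prenatal_association_postnatal_none(self, developmental):
        """tE/I correlates negatively with KCC2/NKCC1 prenatally and shows
        no association postnatally, matching the planted structure."""
        table, meta, truth = developmental
        rec = compute_tei(table, policy="subset")
        tra = transporter_ratios(table)
        out = prepost_correlations(rec["tei"], tra["kcc2_nkcc1"],
                                   meta["age"]).set_index("period")
        assert out.loc["prenatal", "r"] < -0.5
        assert out.loc["prenatal", "p"] < 0.001
        assert abs(out.loc["postnatal", "r"]) < 0.25
        assert out.loc["postnatal", "p"] > 0.01


class TestFitTrend:
    def test_constant_input_gives_constant_curve(self):
        ages = np.linspace(0, 10, 20)
        fit = fit_trend(np.full(20, 3.3), ages)
        np.testing.assert_allclose(fit.curve, 3.3, atol=1e-8)

    def test_noiseless_quadratic_recovered(self):
        ages = np.linspace(-1, 5, 60)
        y = 0.5 * ages ** 2 - ages + 2
        fit = fit_trend(y, ages)
        rms = np.sqrt(np.mean((fit.curve
                               - (0.5 * fit.grid ** 2 - fit.grid + 2)) ** 2))
        assert rms < 1e-3

    def test_no_extrapolation_outside_observed_range(self):
        fit = fit_trend(np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValidationError, match="range"):
            fit(np.array([11.0]))

    def test_plateau_recovery(self, developmental):
        """The fitted post-1-year tE/I plateau lands within 5% of the
        configured adult asymptote 0.31."""
        table, meta, truth = developmental
        rec = compute_tei(table, policy="subset")
        fit = fit_trend(rec["tei"], meta["age"])
        post = fit(np.linspace(1.0, fit.grid[-1], 100))
        assert np.mean(post) == pytest.approx(truth.tei_plateau, rel=0.05)

    def test_insufficient_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_trend([1.0, 2.0], [0.0, 1.0])
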