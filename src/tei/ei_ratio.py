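"""The tE/I statistic and the analyses built on it.

The transcriptional excitation/inhibition ratio of a unit (sample, cell,
subject or region) is the sum of its AMPAR subunit expression divided by
the sum of its GABA_A receptor subunit expression, on the linear scale
(log2 tables are exponentiated base 2 first).  On top of the ratio this
module provides per-group summaries, AMPAR-vs-GABA_A_R total
regressions, Welch and ANOVA + Tukey-Kramer group comparisons, the
KCC2/NKCC1 chloride-transporter ratio, and smoothing-spline
developmental trends with pre/postnatal linear fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from tei.core_io import (
    DEFAULT_PANELS,
    ExpressionTable,
    GenePanel,
    ValidationError,
    resolve_panel,
)

logger = logging.getLogger("tei")

__all__ = [
    "compute_tei",
    "group_summary",
    "regress_totals",
    "compare_groups",
    "transporter_ratios",
    "TrendFit",
    "fit_trend",
    "prepost_correlations",
]


def _panel_sums(table: ExpressionTable, panel: GenePanel, policy: str,
                use_log2_sums: bool) -> pd.Series:
    resolution = resolve_panel(table, panel, policy)
    if use_log2_sums:
        vals = table.values if table.scale == "log2" else np.log2(table.values)
    else:
        vals = table.to_linear().values
    feats = [f for fs in resolution.values() for f in fs]
    return vals[feats].sum(axis=1)


def compute_tei(table: ExpressionTable,
                ampar: GenePanel | None = None,
                gabaar: GenePanel | None = None,
                group_by: list[str] | str | None = None,
                policy: str = "strict",
                use_log2_sums: bool = False) -> pd.DataFrame:
    """Per-sample tE/I records: ΣAMPAR, ΣGABA_A_R and their ratio.

    Sums are on the linear scale by default; ``use_log2_sums`` sums log2
    values instead (sensitivity mode).  Samples with ΣGABA_A_R = 0 get a
    missing ratio with a warning.  Any *group_by* metadata keys are
    carried onto the records for downstream grouping.
    """
    if ampar is None:
        ampar = DEFAULT_PANELS["AMPAR"]
    if gabaar is None:
        gabaar = DEFAULT_PANELS["GABAAR"]
    sum_a = _panel_sums(table, ampar, policy, use_log2_sums)
    sum_g = _panel_sums(table, gabaar, policy, use_log2_sums)
    zero = sum_g == 0
    if zero.any():
        logger.warning("zero GABA_A_R sum in %d sample(s); tE/I missing",
                       int(zero.sum()))
    tei = sum_a / sum_g.where(~zero)
    records = pd.DataFrame({
        "sum_ampar": sum_a, "sum_gabaar": sum_g, "tei": tei,
    })
    keys = [group_by] if isinstance(group_by, str) else list(group_by or [])
    for k in keys:
        if k not in table.sample_meta.columns:
            raise ValidationError(f"unknown metadata key {k!r}")
        records[k] = table.sample_meta[k]
    if "age" in table.sample_meta.columns and "age" not in records.columns:
        records["age"] = table.sample_meta["age"]
    records.attrs["panels"] = {"ampar": ampar.name, "gabaar": gabaar.name}
    return records


def group_summary(records: pd.DataFrame, by: list[str] | str,
                  value: str = "tei") -> pd.DataFrame:
    """n, mean, SD and SEM of *value* per group — the table counterpart of
    every mean ± SEM/SD figure."""
    if isinstance(by, str):
        by = [by]
    g = records.groupby(by, observed=True)[value]
    out = g.agg(n="count", mean="mean", sd="std")
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out.reset_index()


def regress_totals(records: pd.DataFrame, group_by: list[str] | str | None = None,
                   log2: bool = False) -> pd.DataFrame:
    """Per-group OLS of ΣAMPAR on ΣGABA_A_R (optionally log2(x+1) first)."""
    keys = [group_by] if isinstance(group_by, str) else list(group_by or [])
    if keys:
        grouping = records.groupby(keys, observed=True)
    else:
        grouping = [("all", records)]
    rows = []
    for label, sub in grouping:
        x = sub["sum_gabaar"].to_numpy(float)
        y = sub["sum_ampar"].to_numpy(float)
        if log2:
            x, y = np.log2(x + 1.0), np.log2(y + 1.0)
        row = {"group": label if not isinstance(label, tuple) else "|".join(map(str, label)),
               "n": len(sub)}
        if len(sub) < 3 or np.std(x) == 0 or np.std(y) == 0:
            logger.warning("group %s: degenerate regression input", label)
            row.update(slope=np.nan, intercept=np.nan, r=np.nan, p=np.nan)
        else:
            fit = stats.linregress(x, y)
            row.update(slope=fit.slope, intercept=fit.intercept,
                       r=fit.rvalue, p=fit.pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(records: pd.DataFrame, group_key: str,
                   design: str = "anova_tukey_kramer",
                   value: str = "tei") -> pd.DataFrame:
    """Compare *value* between the groups of *group_key*.

    ``welch_two_sample`` runs Welch's unequal-variance t test on every
    pair (t, Satterthwaite df, two-tailed p).  ``anova_tukey_kramer``
    runs a one-way ANOVA and then all pairwise comparisons against
    studentized-range critical values with the Kramer unequal-n
    adjustment; the omnibus F and p are attached as frame attrs.
    """
    groups = {k: v[value].dropna().to_numpy(float)
              for k, v in records.groupby(group_key, observed=True)}
    small = [k for k, v in groups.items() if len(v) < 2]
    if small:
        raise ValidationError(f"group(s) with < 2 units: {small}")
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    names = list(groups)

    rows = []
    if design == "welch_two_sample":
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                res = stats.ttest_ind(groups[a], groups[b], equal_var=False)
                rows.append({"group_a": a, "group_b": b,
                             "t": float(res.statistic), "df": float(res.df),
                             "p": float(res.pvalue)})
        return pd.DataFrame(rows)
    if design == "anova_tukey_kramer":
        f = stats.f_oneway(*groups.values())
        hsd = stats.tukey_hsd(*groups.values())
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                b = names[j]
                rows.append({
                    "group_a": a, "group_b": b,
                    "mean_diff": float(np.mean(groups[a]) - np.mean(groups[b])),
                    "p": float(hsd.pvalue[i, j]),
                })
        out = pd.DataFrame(rows)
        out.attrs["anova_f"] = float(f.statistic)
        out.attrs["anova_p"] = float(f.pvalue)
        return out
    raise ValidationError(f"unknown design {design!r}")


def transporter_ratios(table: ExpressionTable,
                       group_by: list[str] | str | None = None,
                       policy: str = "subset") -> pd.DataFrame:
    """Per-sample chloride-transporter levels and the KCC2/NKCC1 ratio.

    KCC2 is SLC12A5, NKCC1 is SLC12A2, NKCC2 is SLC12A1.  The ratio is
    missing where NKCC1 is zero or either gene is absent.
    """
    panel = DEFAULT_PANELS["TRANSPORTERS"]
    resolution = resolve_panel(table, panel, policy)
    linear = table.to_linear()

    def level(gene):
        feats = resolution.get(gene)
        if not feats:
            return pd.Series(np.nan, index=table.values.index)
        return linear.values[feats].mean(axis=1)

    kcc2, nkcc1, nkcc2 = level("SLC12A5"), level("SLC12A2"), level("SLC12A1")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = kcc2 / nkcc1.where(nkcc1 != 0)
    out = pd.DataFrame({"kcc2": kcc2, "nkcc1": nkcc1, "nkcc2": nkcc2,
                        "kcc2_nkcc1": ratio})
    keys = [group_by] if isinstance(group_by, str) else list(group_by or [])
    for k in keys:
        out[k] = table.sample_meta[k]
    if "age" in table.sample_meta.columns:
        out["age"] = table.sample_meta["age"]
    return out


@dataclass
class TrendFit:
    """A smoothing-spline trend over age, defined on the observed range."""

    grid: np.ndarray
    curve: np.ndarray
    lam: float | None
    spline: object

    def __call__(self, x):
        x = np.asarray(x, float)
        lo, hi = self.grid[0], self.grid[-1]
        if np.any((x < lo) | (x > hi)):
            raise ValidationError("trend evaluated outside the observed age range")
        return self.spline(x)


def fit_trend(values, age, lam: float | None = None,
              n_grid: int = 200) -> TrendFit:
    """Cubic smoothing spline of *values* over *age*.

    The smoothing parameter is chosen by generalized cross-validation
    unless *lam* overrides it.  Duplicate ages are collapsed to their
    weighted mean first (the penalised spline needs strictly increasing
    abscissae).  Requires at least 5 points spanning at least 3 distinct
    ages.
    """
    age = np.asarray(age, float)
    values = np.asarray(values, float)
    ok = np.isfinite(age) & np.isfinite(values)
    age, values = age[ok], values[ok]
    if len(values) < 5 or len(np.unique(age)) < 3:
        raise ValidationError("need >= 5 points over >= 3 distinct ages")
    df = pd.DataFrame({"x": age, "y": values}).groupby("x")["y"]
    xs = df.mean().index.to_numpy(float)
    ys = df.mean().to_numpy(float)
    ws = df.count().to_numpy(float)
    spline = make_smoothing_spline(xs, ys, w=ws, lam=lam)
    grid = np.linspace(xs[0], xs[-1], n_grid)
    return TrendFit(grid, spline(grid), lam, spline)


def prepost_correlations(x, y, age) -> pd.DataFrame:
    """Pearson correlation of x vs y separately pre- and postnatally.

    The split is at birth (age 0, i.e. 40 post-conception weeks);
    samples with age >= 0 count as postnatal.
    """
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float),
                       "age": np.asarray(age, float)}).dropna()
    rows = []
    for label, sub in (("prenatal", df[df["age"] < 0]),
                       ("postnatal", df[df["age"] >= 0])):
        if len(sub) < 3 or sub["x"].std() == 0 or sub["y"].std() == 0:
            rows.append({"period": label, "n": len(sub), "r": np.nan, "p": np.nan})
            continue
        res = stats.pearsonr(sub["x"], sub["y"])
        rows.append({"period": label, "n": len(sub),
                     "r": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows)
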