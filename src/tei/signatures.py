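"""Expression signatures: age adjustment, proportional contributions,
fold enrichment, descriptive summaries, and nested ANOVA.

These are the descriptive and inferential computations applied to the
gene-level table after probe selection: removing linear age effects,
expressing each subunit as a percent of its panel's summed linear-scale
expression per region, ranking substructures by fold enrichment over the
whole-brain mean, box-plot style five-number summaries, and a two-level
fixed-effects nested ANOVA (substructures nested within structures).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tei.core_io import ExpressionTable, GenePanel, ValidationError, resolve_panel

logger = logging.getLogger("tei")

__all__ = [
    "adjust_age",
    "proportional_contribution",
    "fold_enrichment",
    "describe",
    "nested_anova",
    "NestedAnovaResult",
]


def adjust_age(table: ExpressionTable, reference: str = "cohort_mean_age"):
    """Remove per-gene linear age effects.

    Each feature is regressed on age by ordinary least squares; the
    adjusted value is the residual plus the fitted value at the cohort
    mean age, so global expression levels are preserved.  With fewer
    than three distinct ages the design is degenerate and the table is
    passed through with a warning.

    Returns ``(adjusted ExpressionTable, per-feature report DataFrame)``
    with slope, intercept and the slope's t-test p-value.
    """
    if reference != "cohort_mean_age":
        raise ValidationError(f"unknown reference {reference!r}")
    if "age" not in table.sample_meta.columns:
        raise ValidationError("sample metadata lacks an age column")
    age = table.sample_meta["age"].to_numpy(float)
    if len(np.unique(age)) < 3:
        logger.warning("fewer than 3 distinct ages; age adjustment skipped")
        report = pd.DataFrame({
            "feature_id": table.values.columns,
            "slope": 0.0, "intercept": np.nan, "p_value": np.nan,
            "adjusted": False,
        })
        return table, report

    y = table.values.to_numpy(float)
    n = len(age)
    xc = age - age.mean()
    sxx = float(xc @ xc)
    slopes = (xc @ (y - y.mean(axis=0))) / sxx
    intercepts = y.mean(axis=0) - slopes * age.mean()
    fitted = np.outer(age, slopes) + intercepts
    resid = y - fitted
    # slope t-test
    with np.errstate(divide="ignore", invalid="ignore"):
        mse = (resid ** 2).sum(axis=0) / max(n - 2, 1)
        se = np.sqrt(mse / sxx)
        tstat = np.where(se > 0, slopes / se, np.inf * np.sign(slopes))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)

    adjusted = resid + intercepts + slopes * age.mean()
    out = ExpressionTable(
        pd.DataFrame(adjusted, index=table.values.index,
                     columns=table.values.columns),
        table.scale, table.feature_meta, table.sample_meta,
    )
    report = pd.DataFrame({
        "feature_id": table.values.columns,
        "slope": slopes, "intercept": intercepts, "p_value": pvals,
        "adjusted": True,
    })
    return out, report


def _gene_level_linear(table: ExpressionTable, panel: GenePanel,
                       policy: str = "subset") -> pd.DataFrame:
    """Per-sample linear-scale gene values (features averaged within gene)."""
    resolution = resolve_panel(table, panel, policy)
    linear = table.to_linear()
    cols = {}
    for gene, feats in resolution.items():
        cols[gene] = linear.values[feats].mean(axis=1)
    return pd.DataFrame(cols, index=table.values.index)


def proportional_contribution(table: ExpressionTable, panel: GenePanel,
                              group_by: list[str] | str | None = None,
                              policy: str = "strict") -> pd.DataFrame:
    """Percent contribution of each panel gene to the panel's linear sum.

    Log2 tables are exponentiated base 2 first.  Per group, the percent
    for gene g is 100 x mean_linear(g) / sum over panel genes of
    mean_linear.  Groups whose panel sum is zero are emitted as missing
    with a warning.
    """
    genevals = _gene_level_linear(table, panel, policy)
    keys = _normalise_keys(group_by)
    if keys:
        grouped = genevals.groupby(
            [table.sample_meta[k] for k in keys], observed=True, sort=True
        )
        means = grouped.mean()
        counts = grouped.size()
    else:
        means = genevals.mean().to_frame().T
        means.index = pd.Index(["all"], name="group")
        counts = pd.Series([len(genevals)], index=means.index)

    totals = means.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("all-zero panel sum in %d group(s); contributions "
                       "emitted as missing", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * means.div(totals.where(~zero), axis=0)
    pct["n"] = counts
    return pct.reset_index()


def fold_enrichment(table: ExpressionTable, panel: GenePanel,
                    level: str = "substructure",
                    policy: str = "strict") -> pd.DataFrame:
    """Per gene and group: mean log2 expression and fold enrichment.

    Fold enrichment is the linear-scale ratio 2^(group mean log2) /
    2^(global mean log2) — subjects are averaged on the log2 scale
    before exponentiation.  Rows are sorted per gene by descending fold,
    so the top row per gene is its most enriched substructure.
    """
    if level not in table.sample_meta.columns:
        raise ValidationError(f"sample metadata lacks {level!r}")
    resolution = resolve_panel(table, panel, policy)
    if table.scale == "log2":
        logvals = table.values
    else:
        vals = table.values
        if (vals.to_numpy() <= 0).any():
            raise ValidationError("cannot log2-transform non-positive values")
        logvals = np.log2(vals)

    ontology = [k for k in ("region", "structure", "substructure")
                if k in table.sample_meta.columns and k != level]
    rows = []
    labels = table.sample_meta[level]
    for gene, feats in resolution.items():
        g = logvals[feats].mean(axis=1)
        global_mean = g.mean()
        for label, sub in g.groupby(labels, observed=True, sort=True):
            if len(sub) == 0:
                continue
            m = sub.mean()
            row = {"gene": gene, level: label,
                   "log2_mean": m,
                   "fold_enrichment": float(2.0 ** (m - global_mean))}
            for k in ontology:
                parents = table.sample_meta.loc[sub.index, k].dropna().unique()
                row[k] = parents[0] if len(parents) == 1 else None
            rows.append(row)
    out = pd.DataFrame(rows)
    out = out.sort_values(["gene", "fold_enrichment"],
                          ascending=[True, False]).reset_index(drop=True)
    return out


def describe(table: ExpressionTable, panel: GenePanel,
             group_by: list[str] | str | None = None,
             policy: str = "strict"):
    """Box-plot style five-number summary per gene (and group).

    Quantiles use linear interpolation (type 7).  Whiskers extend to
    Q1 - 1.5 IQR and Q3 + 1.5 IQR, clipped to the observed range; points
    beyond them are listed as outliers with their sample and group label.

    Returns ``(summary DataFrame, outliers DataFrame)``.
    """
    resolution = resolve_panel(table, panel, policy)
    keys = _normalise_keys(group_by)
    summaries, outliers = [], []
    for gene, feats in resolution.items():
        g = table.values[feats].mean(axis=1)
        if keys:
            grouping = g.groupby([table.sample_meta[k] for k in keys],
                                 observed=True, sort=True)
        else:
            grouping = [("all", g)]
        for label, sub in grouping:
            q1, med, q3 = np.quantile(sub.to_numpy(), [0.25, 0.5, 0.75])
            iqr = q3 - q1
            lo_f, hi_f = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = sub[(sub >= lo_f) & (sub <= hi_f)]
            lo = inside.min() if len(inside) else sub.min()
            hi = inside.max() if len(inside) else sub.max()
            summaries.append({
                "gene": gene, "group": label, "n": len(sub),
                "median": med, "q1": q1, "q3": q3,
                "whisker_low": lo, "whisker_high": hi,
            })
            out = sub[(sub < lo_f) | (sub > hi_f)]
            for sid, val in out.items():
                outliers.append({"gene": gene, "group": label,
                                 "sample_id": sid, "value": val})
    return pd.DataFrame(summaries), pd.DataFrame(
        outliers, columns=["gene", "group", "sample_id", "value"])


@dataclass
class NestedAnovaResult:
    """Two-level fixed-effects nested decomposition for one gene."""

    gene: str
    ss_structure: float
    ss_substructure: float
    ss_error: float
    ss_total: float
    df_structure: int
    df_substructure: int
    df_error: int
    f_structure: float
    f_substructure: float
    p_structure: float
    p_substructure: float

    def to_dict(self):
        return dict(self.__dict__)


def nested_anova(table: ExpressionTable, gene: str,
                 structure_key: str = "structure",
                 substructure_key: str = "substructure") -> NestedAnovaResult:
    """Nested ANOVA of one gene: substructures nested within structures.

    Fixed-effects decomposition: SS_structure (between structure means),
    SS_substructure (between substructure means within structure) and
    SS_error (within substructures).  F for structure uses the
    substructure mean square as denominator; F for substructure uses the
    error mean square.
    """
    feats = table.features_for_gene(gene)
    if not feats:
        raise ValidationError(f"gene {gene!r} not in table")
    y = table.values[feats].mean(axis=1).to_numpy(float)
    meta = table.sample_meta
    for key in (structure_key, substructure_key):
        if key not in meta.columns:
            raise ValidationError(f"sample metadata lacks {key!r}")
    struct = meta[structure_key].to_numpy()
    sub = meta[substructure_key].to_numpy()

    structures = pd.unique(struct)
    if len(structures) < 2:
        raise ValidationError("need >= 2 structures")

    grand = y.mean()
    ss_structure = ss_sub = ss_err = 0.0
    df_sub = df_err = 0
    n_sub_total = 0
    any_nesting = False
    for s in structures:
        ms = struct == s
        ys = y[ms]
        smean = ys.mean()
        ss_structure += len(ys) * (smean - grand) ** 2
        subs = pd.unique(sub[ms])
        if len(subs) > 1:
            any_nesting = True
        n_sub_total += len(subs)
        df_sub += len(subs) - 1
        for b in subs:
            mb = ms & (sub == b)
            yb = y[mb]
            bmean = yb.mean()
            ss_sub += len(yb) * (bmean - smean) ** 2
            ss_err += float(((yb - bmean) ** 2).sum())
            df_err += len(yb) - 1
    if not any_nesting:
        raise ValidationError("no structure has >= 2 substructures")
    if df_err == 0:
        raise ValidationError(
            "saturated design: no replicate within any substructure "
            "(deficient level: substructure)")
    if df_sub == 0:
        raise ValidationError("deficient level: substructure (no df)")

    df_structure = len(structures) - 1
    ms_structure = ss_structure / df_structure
    ms_sub = ss_sub / df_sub
    ms_err = ss_err / df_err
    f_structure = ms_structure / ms_sub if ms_sub > 0 else np.inf
    f_sub = ms_sub / ms_err if ms_err > 0 else np.inf
    return NestedAnovaResult(
        gene=gene,
        ss_structure=ss_structure, ss_substructure=ss_sub, ss_error=ss_err,
        ss_total=float(((y - grand) ** 2).sum()),
        df_structure=df_structure, df_substructure=df_sub, df_error=df_err,
        f_structure=f_structure, f_substructure=f_sub,
        p_structure=float(stats.f.sf(f_structure, df_structure, df_sub)),
        p_substructure=float(stats.f.sf(f_sub, df_sub, df_err)),
    )


def _normalise_keys(group_by) -> list[str]:
    if group_by is None:
        return []
    if isinstance(group_by, str):
        return [group_by]
    return list(group_by)
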