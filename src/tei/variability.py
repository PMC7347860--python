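"""Inter-individual and inter-structure variability of subunit signatures.

The collective organisation of a receptor panel in one unit (a subject x
structure combination, or a whole structure) is summarised by the vector
of pairwise Euclidean distances between its per-gene expression values:
for scalar values the distance between genes x and y reduces to |x - y|.
Each unit's vector is then correlated (Pearson) against a consensus
vector — the average over subjects, or a chosen reference structure — so
a unit similar in shape to the consensus scores R near 1, and structures
whose subjects disagree show a low, spread R.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from tei.core_io import ExpressionTable, GenePanel, ValidationError, resolve_panel

logger = logging.getLogger("tei")

__all__ = [
    "pair_labels",
    "subunit_distance_vector",
    "distance_vectors",
    "consensus_distances",
    "correlate_to_consensus",
]


def pair_labels(genes) -> list[str]:
    """Ordered unordered-pair labels: (1,2),(1,3),...,(k-1,k)."""
    return [f"{a}-{b}" for a, b in itertools.combinations(genes, 2)]


def subunit_distance_vector(values) -> np.ndarray:
    """Pairwise distances |x - y| over all gene pairs, in fixed pair order.

    *values* is an ordered mapping or sequence of per-gene scalars (or
    1-D vectors, in which case each entry is the Euclidean distance
    between the two genes' vectors).
    """
    if isinstance(values, dict):
        vals = list(values.values())
    else:
        vals = list(values)
    if len(vals) < 2:
        raise ValidationError("need at least 2 genes")
    out = []
    for x, y in itertools.combinations(vals, 2):
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValidationError("non-finite expression value")
        out.append(float(np.sqrt(((x - y) ** 2).sum())))
    return np.asarray(out)


def distance_vectors(table: ExpressionTable, panel: GenePanel,
                     unit_keys: list[str] | str,
                     policy: str = "strict") -> pd.DataFrame:
    """Per-unit distance vectors from an expression table.

    Units are groups of the named metadata keys (e.g. ``["subject_id",
    "substructure"]``); per unit, each gene's value is the mean over the
    unit's samples (features averaged within gene first).  Returns a
    DataFrame indexed by the unit keys with one column per gene pair.
    """
    if isinstance(unit_keys, str):
        unit_keys = [unit_keys]
    for k in unit_keys:
        if k not in table.sample_meta.columns:
            raise ValidationError(f"unknown metadata key {k!r}")
    resolution = resolve_panel(table, panel, policy)
    genes = list(resolution)
    genevals = pd.DataFrame(
        {g: table.values[feats].mean(axis=1) for g, feats in resolution.items()},
        index=table.values.index,
    )
    grouped = genevals.groupby([table.sample_meta[k] for k in unit_keys],
                               observed=True, sort=True).mean()
    cols = pair_labels(genes)
    rows = [subunit_distance_vector(row.to_numpy()) for _, row in grouped.iterrows()]
    out = pd.DataFrame(rows, index=grouped.index, columns=cols)
    out.index.names = unit_keys
    return out


def consensus_distances(units: pd.DataFrame, mode: str = "average_of_units",
                        reference: str | None = None,
                        reference_level: str | None = None) -> pd.Series:
    """Build the consensus distance vector d_c from per-unit vectors.

    ``average_of_units`` takes the elementwise mean of the unit vectors;
    ``pooled_eq2`` takes the elementwise square root of the sum of
    squared per-unit distances.  When *reference* is given, only units
    whose *reference_level* index equals it contribute (e.g. a single
    reference structure).
    """
    if len(units) == 0:
        raise ValidationError("no units")
    sel = units
    if reference is not None:
        if reference_level is None:
            reference_level = units.index.names[-1]
        mask = units.index.get_level_values(reference_level) == reference
        sel = units[mask]
        if len(sel) == 0:
            raise ValidationError(f"no units with {reference_level}={reference!r}")
    if mode == "average_of_units":
        return sel.mean(axis=0)
    if mode == "pooled_eq2":
        return pd.Series(np.sqrt((sel ** 2).sum(axis=0)), index=sel.columns)
    raise ValidationError(f"unknown consensus mode {mode!r}")


def correlate_to_consensus(units: pd.DataFrame, consensus: pd.Series,
                           group_level: str | None = None):
    """Pearson R of every unit's distance vector against the consensus.

    Units whose vector (or the consensus) has zero variance get a
    missing R with a warning.  Returns ``(per-unit DataFrame with an R
    column, group summary with mean/SD/n per *group_level*)``; the
    summary is None when no group level is given or present.
    """
    if units.shape[1] < 3:
        raise ValidationError("need >= 3 distance pairs to correlate")
    c = consensus.to_numpy(float)
    if np.std(c) == 0:
        logger.warning("consensus vector has zero variance; all R missing")
    rs = []
    for _, row in units.iterrows():
        v = row.to_numpy(float)
        if np.std(v) == 0 or np.std(c) == 0:
            rs.append(np.nan)
        else:
            rs.append(float(stats.pearsonr(v, c).statistic))
    n_missing = int(np.isnan(rs).sum())
    if n_missing:
        logger.warning("%d unit(s) with zero-variance vector; R missing",
                       n_missing)
    out = units.copy()
    out["R"] = rs

    summary = None
    if group_level is not None and group_level in (units.index.names or []):
        g = out.groupby(level=group_level, observed=True)["R"]
        summary = g.agg(["mean", "std", "count"]).rename(
            columns={"mean": "mean_R", "std": "sd_R", "count": "n"})
    return out, summary
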