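"""Representative-probe selection by principal-axis factor analysis.

Microarray designs carry several probes per gene; their intensities are
collinear, which would distort any clustering run at the probe level.
The pipeline therefore extracts a single factor per gene from the probe x
probe Pearson correlation matrix (principal-axis factoring, no rotation)
and keeps the probe with the largest absolute loading — the probe most
representative of the gene's shared expression signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from tei.core_io import ExpressionTable, ValidationError

logger = logging.getLogger("tei")

__all__ = ["FactorResult", "principal_axis_factor", "select_representative_probes"]


@dataclass
class FactorResult:
    """Single-factor principal-axis solution for one gene's probes."""

    gene: str
    probe_ids: list[str]
    loadings: np.ndarray
    communalities: np.ndarray
    iterations: int
    converged: bool
    selected_probe: str | None = None


def _initial_communalities(corr: np.ndarray) -> np.ndarray:
    """Squared multiple correlations, 1 - 1/diag(R^-1).

    Falls back to the max absolute off-diagonal correlation per row when
    the matrix is singular.
    """
    p = corr.shape[0]
    try:
        inv = np.linalg.inv(corr)
        diag = np.diag(inv)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive inverse diagonal")
        return 1.0 - 1.0 / diag
    except np.linalg.LinAlgError:
        logger.warning("singular correlation matrix; initialising "
                       "communalities from max |r| per row")
        off = np.abs(corr - np.eye(p))
        return off.max(axis=1)


def principal_axis_factor(corr: np.ndarray, tol: float = 1e-10,
                          max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Extract one factor by iterated principal-axis factoring.

    Communalities start at the squared multiple correlations and the
    correlation diagonal is repeatedly replaced by them; at each step the
    loading vector is the leading eigenvector scaled by the square root
    of the leading eigenvalue, and the communalities are the squared
    loadings.  Iteration stops when the largest communality change drops
    below *tol*.  Loadings are sign-flipped so their sum is >= 0.
    Heywood cases (communality > 1) are clipped just below 1.

    Returns ``(loadings, communalities, iterations, converged)``.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValidationError("correlation matrix must be square")
    p = corr.shape[0]
    if p == 0:
        raise ValidationError("empty correlation matrix")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValidationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValidationError("correlation matrix must have unit diagonal")
    if p == 1:
        return np.array([1.0]), np.array([1.0]), 0, True

    h = np.clip(_initial_communalities(corr), 0.0, 1.0 - 1e-12)
    loadings = np.sqrt(h)
    converged = False
    heywood = False
    it = 0
    for it in range(1, max_iter + 1):
        reduced = corr.copy()
        np.fill_diagonal(reduced, h)
        eigvals, eigvecs = np.linalg.eigh(reduced)
        lead = max(eigvals[-1], 0.0)
        loadings = eigvecs[:, -1] * np.sqrt(lead)
        h_new = loadings ** 2
        if np.any(h_new > 1.0):
            heywood = True
            h_new = np.minimum(h_new, 1.0 - 1e-12)
        delta = np.max(np.abs(h_new - h))
        h = h_new
        if delta < tol:
            converged = True
            break
    if heywood:
        logger.warning("Heywood case encountered: communalities clipped to 1")
    if loadings.sum() < 0:
        loadings = -loadings
    return loadings, h, it, converged


def _probe_correlation(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation across samples; flags zero-variance probes."""
    sd = values.std(axis=0)
    usable = sd > 0
    corr = np.eye(values.shape[1])
    if usable.sum() >= 2:
        sub = np.corrcoef(values[:, usable], rowvar=False)
        idx = np.flatnonzero(usable)
        corr[np.ix_(idx, idx)] = sub
    return corr, usable


def select_representative_probes(table: ExpressionTable,
                                 group_by: str | None = None,
                                 tol: float = 1e-10,
                                 max_iter: int = 1000):
    """Pick the max-|loading| probe per gene and build a gene-level table.

    Correlations are computed across all samples (whole brain) by
    default; *group_by* restricts them to within-group correlations
    averaged over groups of the named metadata key.  Ties on |loading|
    (within 1e-9) are broken by higher mean intensity, then by
    lexicographic probe id.  Zero-variance probes are excluded from the
    correlation (selected only when they are the sole candidate).

    Returns ``(selection report DataFrame, gene-level ExpressionTable,
    list of FactorResult)``.
    """
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples to correlate probes")

    results: list[FactorResult] = []
    report_rows = []
    selected: dict[str, str] = {}
    gene_map = table.gene_map

    for gene in table.genes():
        probes = table.features_for_gene(gene)
        vals = table.values[probes].to_numpy()
        means = vals.mean(axis=0)

        if len(probes) == 1:
            res = FactorResult(gene, probes, np.array([1.0]), np.array([1.0]),
                               0, True, probes[0])
        else:
            corr, usable = _probe_correlation(_grouped_values(table, probes, group_by))
            if not usable.all():
                logger.warning("gene %s: %d zero-variance probe(s) excluded "
                               "from the correlation", gene, int((~usable).sum()))
            use_idx = np.flatnonzero(usable)
            loadings = np.zeros(len(probes))
            comms = np.zeros(len(probes))
            if len(use_idx) == 0:
                it, conv = 0, True
            elif len(use_idx) == 1:
                loadings[use_idx[0]] = 1.0
                comms[use_idx[0]] = 1.0
                it, conv = 0, True
            else:
                sub = corr[np.ix_(use_idx, use_idx)]
                lam, h, it, conv = principal_axis_factor(sub, tol, max_iter)
                loadings[use_idx] = lam
                comms[use_idx] = h
            res = FactorResult(gene, probes, loadings, comms, it, conv)
            # argmax |loading| with documented tie-break
            order = sorted(
                range(len(probes)),
                key=lambda i: (-round(abs(res.loadings[i]) / 1e-9),
                               -means[i], probes[i]),
            )
            res.selected_probe = probes[order[0]]

        selected[gene] = res.selected_probe
        results.append(res)
        best_abs = np.abs(res.loadings).max() if len(res.loadings) else 0.0
        for i, probe in enumerate(res.probe_ids):
            tie = (abs(abs(res.loadings[i]) - best_abs) < 1e-9
                   and probe != res.selected_probe)
            report_rows.append({
                "gene": gene,
                "probe": probe,
                "loading": res.loadings[i],
                "communality": res.communalities[i],
                "mean_intensity": means[i],
                "selected": probe == res.selected_probe,
                "tie_break_used": bool(tie) or (
                    probe == res.selected_probe
                    and sum(abs(abs(l) - best_abs) < 1e-9
                            for l in res.loadings) > 1),
            })

    report = pd.DataFrame(report_rows)
    gene_values = table.values[[selected[g] for g in selected]].copy()
    gene_values.columns = list(selected)
    reduced = ExpressionTable(gene_values, table.scale, None, table.sample_meta)
    return report, reduced, results


def _grouped_values(table: ExpressionTable, probes: list[str],
                    group_by: str | None) -> np.ndarray:
    """Values for correlation; group_by centres within groups first."""
    vals = table.values[probes].to_numpy()
    if group_by is None:
        return vals
    if group_by not in table.sample_meta.columns:
        raise ValidationError(f"unknown metadata key {group_by!r}")
    groups = table.sample_meta[group_by].to_numpy()
    out = vals.astype(float).copy()
    for g in pd.unique(groups):
        m = groups == g
        out[m] -= out[m].mean(axis=0)
    return out
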