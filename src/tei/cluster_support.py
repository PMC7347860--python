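"""Ward hierarchical clustering with multiscale-bootstrap cluster support.

Brain structures (or genes, on the transposed matrix) are clustered by
Ward's minimum-variance method on Euclidean distances (the ward.D2
convention: merge heights are the square roots of the within-cluster
variance increments).  The strength of every internal node is then
quantified by two support values obtained from feature resampling:

* **BP** — the naive bootstrap probability: the fraction of same-size
  resamples of the feature axis in which the node's leaf set reappears
  as a cluster.
* **AU** — the approximately unbiased p-value: resampling is repeated at
  several sample-size scales r (default 0.5 … 1.4), the per-scale
  recurrence probabilities BP_r are mapped through the normal quantile
  ψ(r) = Φ⁻¹(1 − BP_r), and a two-parameter curve ψ(r) ≈ v·√r + c/√r is
  fitted by weighted least squares; AU = 1 − Φ(v − c).  AU corrects the
  well-known conservative bias of BP for clusters with many competing
  rearrangements.

Cluster recurrence is judged by leaf-set identity, so it is invariant to
child order inside the dendrogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import norm

from tei.core_io import ValidationError

logger = logging.getLogger("tei")

__all__ = [
    "Dendrogram",
    "BootstrapConfig",
    "NodeSupport",
    "ClusterSupport",
    "ward_cluster",
    "cluster_leaf_sets",
    "fit_au_bp",
    "multiscale_bootstrap",
]


@dataclass
class Dendrogram:
    """A Ward dendrogram: scipy linkage matrix plus leaf labels.

    Heights follow the ward.D2 convention (square-root scale) and are
    non-decreasing along the merge sequence.  Ties in the merge order
    are resolved deterministically by input order (the nearest-neighbor
    chain order of the linkage algorithm).
    """

    linkage: np.ndarray  # scipy (m-1) x 4 linkage matrix
    labels: list[str]
    linkage_tag: str = "ward_d2"
    distance_tag: str = "euclidean"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self, support: dict[frozenset, float] | None = None) -> str:
        """Newick string; internal nodes optionally annotated with support."""
        n = self.n_leaves
        children: dict[int, tuple[int, int]] = {}
        for i, (a, b, _h, _c) in enumerate(self.linkage):
            children[n + i] = (int(a), int(b))

        leafsets = cluster_leaf_sets(self.linkage, self.labels)

        def render(node: int) -> str:
            if node < n:
                return self.labels[node].replace(" ", "_")
            a, b = children[node]
            h = self.linkage[node - n, 2]
            label = ""
            if support is not None:
                ls = leafsets[node - n]
                if ls in support:
                    label = f"{support[ls]:.3f}"
            return f"({render(a)},{render(b)}){label}:{h:.6g}"

        return render(n + len(children) - 1) + ";"


def ward_cluster(matrix, labels: list[str] | None = None) -> Dendrogram:
    """Ward (ward.D2) agglomerative clustering of rows on Euclidean distance."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValidationError("expected a 2-D items x features matrix")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 items to cluster")
    if np.isnan(X).any():
        raise ValidationError("missing values in clustering input")
    if labels is None:
        labels = [str(i) for i in range(X.shape[0])]
    if len(labels) != X.shape[0]:
        raise ValidationError("label count does not match row count")
    Z = hierarchy.linkage(X, method="ward")
    return Dendrogram(Z, list(labels))


def cluster_leaf_sets(Z: np.ndarray, labels: list[str]) -> list[frozenset]:
    """Leaf-label set of every internal node, in merge order."""
    n = len(labels)
    sets: list[frozenset] = []
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    for i, (a, b, _h, _c) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        sets.append(merged)
    return sets


@dataclass
class BootstrapConfig:
    """Multiscale bootstrap settings.

    ``scales`` are relative resample sizes r; at each, ``b_per_scale``
    resamples of round(r x n features) are drawn with replacement.  The
    production default mirrors a 10,000-replicate budget split evenly
    over ten scales.
    """

    scales: tuple = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4)
    b_per_scale: int = 1000
    seed: int = 0

    def validate(self):
        if any(r <= 0 for r in self.scales):
            raise ValidationError("scales must be positive")
        if self.b_per_scale < 1:
            raise ValidationError("need at least 1 bootstrap per scale")


@dataclass
class NodeSupport:
    """Support values for one internal node."""

    node: int
    leaf_set: frozenset
    bp: float
    au: float | None
    v: float | None
    c: float | None
    se_au: float | None
    counts: dict = field(default_factory=dict)  # scale -> recurrence count


def fit_au_bp(counts, scales, b_per_scale: int):
    """Fit (BP, AU, v, c, se_AU) from per-scale recurrence counts.

    *counts* are the number of resamples (out of *b_per_scale*) in which
    the cluster recurred at each scale.  BP is the recurrence fraction
    at the scale closest to 1.  Counts are clamped with a 0.5/B
    continuity correction, mapped through ψ(r) = Φ⁻¹(1 − BP_r), and the
    curve ψ ≈ v·√r + c/√r is fitted by binomial-weighted least squares;
    AU = 1 − Φ(v − c).  A cluster recurring in every resample at every
    scale gets BP = AU = 1 exactly.  AU is None when fewer than 3 scales
    are usable.
    """
    raw = np.asarray(counts, dtype=float)
    scales = np.asarray(scales, dtype=float)
    B = b_per_scale
    bp_scale = int(np.argmin(np.abs(scales - 1.0)))
    bp = raw[bp_scale] / B
    if np.all(raw == B):
        return 1.0, 1.0, None, None, 0.0
    clamped = np.clip(raw, 0.5, B - 0.5)
    bp_r = clamped / B
    psi = norm.ppf(1.0 - bp_r)
    sqrt_r = np.sqrt(scales)

    usable = np.isfinite(psi)
    au = v = c = se_au = None
    if usable.sum() >= 3:
        A = np.column_stack([sqrt_r[usable], 1.0 / sqrt_r[usable]])
        y = psi[usable]
        # delta-method variance of psi: p(1-p) / (B * phi(psi)^2)
        phi = norm.pdf(psi[usable])
        var = bp_r[usable] * (1 - bp_r[usable]) / (B * phi ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = 1.0 / var
        if not np.all(np.isfinite(w)):
            logger.warning("non-finite WLS weights; falling back to "
                           "unweighted fit")
            w = np.ones_like(y)
        Aw = A * np.sqrt(w)[:, None]
        yw = y * np.sqrt(w)
        coef, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
        v, c = float(coef[0]), float(coef[1])
        au = float(1.0 - norm.cdf(v - c))
        try:
            cov = np.linalg.inv(Aw.T @ Aw)
            var_vc = float(np.array([1.0, -1.0]) @ cov @ np.array([1.0, -1.0]))
            se_au = float(norm.pdf(v - c) * np.sqrt(max(var_vc, 0.0)))
        except np.linalg.LinAlgError:
            se_au = None
    else:
        logger.warning("fewer than 3 usable scales; AU missing")
    return float(bp), au, v, c, se_au


@dataclass
class ClusterSupport:
    """Dendrogram plus per-node BP/AU support and fit diagnostics."""

    dendrogram: Dendrogram
    nodes: list[NodeSupport]
    config: BootstrapConfig

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for ns in self.nodes:
            rows.append({
                "node": ns.node,
                "leaf_set": "|".join(sorted(ns.leaf_set)),
                "n_leaves": len(ns.leaf_set),
                "bp": ns.bp, "au": ns.au,
                "v": ns.v, "c": ns.c, "se_au": ns.se_au,
            })
        return pd.DataFrame(rows)

    def support_map(self, which: str = "au") -> dict[frozenset, float]:
        return {ns.leaf_set: getattr(ns, which) for ns in self.nodes
                if getattr(ns, which) is not None}


def multiscale_bootstrap(matrix, cfg: BootstrapConfig,
                         labels: list[str] | None = None,
                         dendrogram: Dendrogram | None = None) -> ClusterSupport:
    """Multiscale bootstrap of a Ward dendrogram's clusters.

    Features (columns) are resampled with replacement at every scale in
    ``cfg.scales``; rows are re-clustered and each reference cluster's
    recurrence is counted.  Extreme counts are clamped with a 0.5/B
    continuity correction before the normal-quantile transform.  The
    (v, c) curve fit uses binomial delta-method weights, falling back to
    unweighted least squares if any weight is non-finite.  AU is set
    missing (with BP still reported) when fewer than 3 scales are usable.
    """
    cfg.validate()
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValidationError("need an items x features matrix with >= 2 features")
    if dendrogram is None:
        dendrogram = ward_cluster(X, labels)
    labels = dendrogram.labels
    n_items, n_feat = X.shape

    ref_sets = cluster_leaf_sets(dendrogram.linkage, labels)
    ref_index = {s: i for i, s in enumerate(ref_sets)}
    n_nodes = len(ref_sets)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xB007]))
    scales = tuple(cfg.scales)
    counts = np.zeros((n_nodes, len(scales)), dtype=np.int64)

    for si, r in enumerate(scales):
        m = max(int(round(r * n_feat)), 1)
        for _ in range(cfg.b_per_scale):
            cols = rng.integers(0, n_feat, size=m)
            Zb = hierarchy.linkage(X[:, cols], method="ward")
            for s in cluster_leaf_sets(Zb, labels):
                idx = ref_index.get(s)
                if idx is not None:
                    counts[idx, si] += 1

    nodes: list[NodeSupport] = []
    for i, leaf_set in enumerate(ref_sets):
        raw = counts[i].astype(float)
        bp, au, v, c, se_au = fit_au_bp(raw, scales, cfg.b_per_scale)
        nodes.append(NodeSupport(i, leaf_set, bp, au, v, c, se_au,
                                 dict(zip(scales, raw))))

    return ClusterSupport(dendrogram, nodes, cfg)
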