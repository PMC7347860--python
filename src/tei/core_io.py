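"""Data model, file I/O and gene-panel configuration.

The central container is :class:`ExpressionTable`: a samples x features
numeric matrix with a declared scale (``log2`` or ``linear``), per-feature
gene mapping, and per-sample metadata (subject, age, sex, and an optional
three-level region / structure / substructure ontology, or a cell type).

Gene panels drive every downstream sum and ratio.  The defaults are the
four AMPAR subunit genes (GRIA1-4), the 19 GABA_A receptor subunit genes
(GABR*), and the three cation-chloride cotransporters (SLC12A1/2/5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("tei")

__all__ = [
    "ValidationError",
    "MissingGeneError",
    "GenePanel",
    "DEFAULT_PANELS",
    "Dialect",
    "ExpressionTable",
    "read_expression_table",
    "write_expression_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "resolve_panel",
    "load_panels",
]


class ValidationError(ValueError):
    """A table or its metadata violates a structural invariant."""


class MissingGeneError(ValidationError):
    """A strict panel resolution found absent genes."""

    def __init__(self, panel: str, missing: list[str]):
        self.panel = panel
        self.missing = list(missing)
        super().__init__(
            f"panel {panel!r}: genes absent from table: {', '.join(self.missing)}"
        )


@dataclass(frozen=True)
class GenePanel:
    """A named, ordered list of gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        genes = tuple(self.genes)
        if not genes:
            raise ValidationError(f"panel {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValidationError(f"panel {self.name!r} has duplicate symbols")
        object.__setattr__(self, "genes", genes)

    def __iter__(self):
        return iter(self.genes)

    def __len__(self):
        return len(self.genes)


AMPAR_GENES = ("GRIA1", "GRIA2", "GRIA3", "GRIA4")
# The 19 GABA_A receptor subunit genes; whether the rho subunits (GABRR1-3)
# belong in the inhibitory sum is debatable, so the panel is configurable.
GABAAR_GENES = (
    "GABRA1", "GABRA2", "GABRA3", "GABRA4", "GABRA5", "GABRA6",
    "GABRB1", "GABRB2", "GABRB3",
    "GABRG1", "GABRG2", "GABRG3",
    "GABRD", "GABRE", "GABRP", "GABRQ",
    "GABRR1", "GABRR2", "GABRR3",
)
TRANSPORTER_GENES = ("SLC12A1", "SLC12A2", "SLC12A5")

DEFAULT_PANELS: dict[str, GenePanel] = {
    "AMPAR": GenePanel("AMPAR", AMPAR_GENES),
    "GABAAR": GenePanel("GABAAR", GABAAR_GENES),
    "TRANSPORTERS": GenePanel("TRANSPORTERS", TRANSPORTER_GENES),
}

#: Metadata columns recognised on samples.  ``age`` is in years; prenatal
#: ages are negative (birth at 40 post-conception weeks = 0).
SAMPLE_META_COLUMNS = (
    "subject_id", "age", "sex", "region", "structure", "substructure", "cell_type",
)

ONTOLOGY_KEYS = ("region", "structure", "substructure")


@dataclass(frozen=True)
class Dialect:
    """How to read a delimited expression file.

    The scale is always declared, never inferred: silently mis-scaling a
    log2 table corrupts every ratio downstream.
    """

    scale: str  # "log2" | "linear"
    orientation: str = "features_in_rows"  # or "features_in_columns"
    sep: str = "\t"
    sample_id_column: str = "sample_id"
    feature_id_column: str = "feature_id"
    gene_column: str = "gene_symbol"
    missing_policy: str = "error"  # "error" | "drop_sample" | "drop_feature"

    def __post_init__(self):
        if self.scale not in ("log2", "linear"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.orientation not in ("features_in_rows", "features_in_columns"):
            raise ValidationError(f"unknown orientation {self.orientation!r}")
        if self.missing_policy not in ("error", "drop_sample", "drop_feature"):
            raise ValidationError(f"unknown missing policy {self.missing_policy!r}")


class ExpressionTable:
    """Samples x features expression matrix with metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with feature ids as columns.
    scale
        ``"log2"`` or ``"linear"``.  Linear tables must be non-negative.
    feature_meta
        DataFrame indexed by feature id with a ``gene_symbol`` column.
        If omitted, features are assumed gene-level (feature id == gene).
    sample_meta
        DataFrame indexed by sample id; any of ``subject_id, age, sex,
        region, structure, substructure, cell_type``.
    """

    def __init__(self, values: pd.DataFrame, scale: str,
                 feature_meta: pd.DataFrame | None = None,
                 sample_meta: pd.DataFrame | None = None):
        if scale not in ("log2", "linear"):
            raise ValidationError(f"unknown scale {scale!r}")
        values = values.astype(float)
        if values.index.has_duplicates:
            raise ValidationError("duplicate sample ids")
        if values.columns.has_duplicates:
            raise ValidationError("duplicate feature ids")
        if values.isna().any().any():
            raise ValidationError("missing values in expression matrix")
        if scale == "linear" and (values.to_numpy() < 0).any():
            raise ValidationError("negative value in linear-scale table")

        if feature_meta is None:
            feature_meta = pd.DataFrame(
                {"gene_symbol": list(values.columns)}, index=values.columns
            )
        else:
            feature_meta = feature_meta.copy()
            if "gene_symbol" not in feature_meta.columns:
                raise ValidationError("feature_meta lacks gene_symbol column")
            missing = values.columns.difference(feature_meta.index)
            if len(missing):
                raise ValidationError(
                    f"features without gene mapping: {list(missing)[:5]}"
                )
            feature_meta = feature_meta.loc[values.columns]
            if feature_meta["gene_symbol"].isna().any():
                raise ValidationError("feature with null gene_symbol")

        if sample_meta is None:
            sample_meta = pd.DataFrame(index=values.index)
        else:
            sample_meta = sample_meta.copy()
            missing = values.index.difference(sample_meta.index)
            if len(missing):
                raise ValidationError(
                    f"samples without metadata: {list(missing)[:5]}"
                )
            sample_meta = sample_meta.loc[values.index]
            _validate_ontology(sample_meta)

        self.values = values
        self.scale = scale
        self.feature_meta = feature_meta
        self.sample_meta = sample_meta

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def gene_map(self) -> pd.Series:
        """feature id -> gene symbol."""
        return self.feature_meta["gene_symbol"]

    def features_for_gene(self, gene: str) -> list[str]:
        m = self.gene_map
        return list(m.index[m == gene])

    def genes(self) -> list[str]:
        return list(pd.unique(self.gene_map))

    def is_gene_level(self) -> bool:
        return not self.gene_map.duplicated().any()

    def to_linear(self) -> "ExpressionTable":
        """Return a linear-scale view (log2 tables are exponentiated base 2)."""
        if self.scale == "linear":
            return self
        return ExpressionTable(
            np.exp2(self.values), "linear", self.feature_meta, self.sample_meta
        )

    def subset_features(self, feature_ids) -> "ExpressionTable":
        feature_ids = list(feature_ids)
        return ExpressionTable(
            self.values[feature_ids], self.scale,
            self.feature_meta.loc[feature_ids], self.sample_meta,
        )

    def subset_samples(self, sample_ids) -> "ExpressionTable":
        sample_ids = list(sample_ids)
        return ExpressionTable(
            self.values.loc[sample_ids], self.scale,
            self.feature_meta, self.sample_meta.loc[sample_ids],
        )

    def __repr__(self):
        return (f"ExpressionTable({self.n_samples} samples x "
                f"{self.n_features} features, scale={self.scale})")


def _validate_ontology(meta: pd.DataFrame) -> None:
    """Substructure -> structure -> region nesting must be a function."""
    for child, parent in (("substructure", "structure"), ("structure", "region")):
        if child in meta.columns and parent in meta.columns:
            sub = meta[[child, parent]].dropna()
            n_parents = sub.groupby(child)[parent].nunique()
            bad = n_parents[n_parents > 1]
            if len(bad):
                raise ValidationError(
                    f"{child} mapped to multiple {parent}s: {list(bad.index)[:5]}"
                )


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_expression_table(path, dialect: Dialect,
                          sample_meta: pd.DataFrame | None = None) -> ExpressionTable:
    """Read a delimited expression matrix.

    With ``features_in_rows`` the file carries feature id and gene symbol
    columns followed by one column per sample.  With
    ``features_in_columns`` rows are samples (id in ``sample_id_column``)
    and columns are gene-level features.

    Rows or columns containing missing entries are rejected (policy
    ``error``) or dropped (``drop_sample`` / ``drop_feature``); either way
    the action is logged.
    """
    raw = pd.read_csv(path, sep=dialect.sep)
    if dialect.orientation == "features_in_rows":
        for col in (dialect.feature_id_column, dialect.gene_column):
            if col not in raw.columns:
                raise ValidationError(f"{path}: missing column {col!r} in header")
        if raw[dialect.feature_id_column].duplicated().any():
            raise ValidationError(f"{path}: duplicate feature ids")
        feature_meta = pd.DataFrame(
            {"gene_symbol": raw[dialect.gene_column].to_numpy()},
            index=pd.Index(raw[dialect.feature_id_column], name="feature_id"),
        )
        values = raw.drop(columns=[dialect.feature_id_column, dialect.gene_column])
        try:
            values = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: non-numeric expression value: {exc}")
        values.index = feature_meta.index
        values = values.T
        values.index.name = "sample_id"
    else:
        if dialect.sample_id_column not in raw.columns:
            raise ValidationError(
                f"{path}: missing column {dialect.sample_id_column!r} in header"
            )
        raw = raw.set_index(dialect.sample_id_column)
        if raw.index.has_duplicates:
            raise ValidationError(f"{path}: duplicate sample ids")
        values = raw.astype(float)
        feature_meta = None

    values = _apply_missing_policy(values, dialect.missing_policy, str(path))
    if feature_meta is not None:
        feature_meta = feature_meta.loc[values.columns]
    table = ExpressionTable(values, dialect.scale, feature_meta, sample_meta)
    logger.info("read %s: %d samples x %d features (%s scale)",
                path, table.n_samples, table.n_features, table.scale)
    return table


def _apply_missing_policy(values: pd.DataFrame, policy: str, source: str) -> pd.DataFrame:
    n_missing = int(values.isna().sum().sum())
    if n_missing == 0:
        return values
    if policy == "error":
        raise ValidationError(f"{source}: {n_missing} missing value(s)")
    if policy == "drop_feature":
        keep = ~values.isna().any(axis=0)
        dropped = list(values.columns[~keep])
        values = values.loc[:, keep]
    else:  # drop_sample
        keep = ~values.isna().any(axis=1)
        dropped = list(values.index[~keep])
        values = values.loc[keep]
    logger.warning("%s: dropped %d %s(s) with missing entries: %s",
                   source, len(dropped),
                   "feature" if policy == "drop_feature" else "sample",
                   dropped[:10])
    return values


def write_expression_table(table: ExpressionTable, path,
                           orientation: str = "features_in_rows",
                           sep: str = "\t") -> None:
    """Write a table in the same dialect :func:`read_expression_table` reads.

    Full float precision is kept so a round trip reproduces values exactly.
    """
    if orientation == "features_in_rows":
        out = table.values.T
        out.insert(0, "gene_symbol", table.gene_map.loc[out.index].to_numpy())
        out.insert(0, "feature_id", out.index.to_numpy())
        out.to_csv(path, sep=sep, index=False, float_format="%.17g")
    else:
        out = table.values.copy()
        out.insert(0, "sample_id", out.index.to_numpy())
        out.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_sample_metadata(path, sep: str = "\t") -> pd.DataFrame:
    meta = pd.read_csv(path, sep=sep)
    if "sample_id" not in meta.columns:
        raise ValidationError(f"{path}: missing sample_id column")
    if meta["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    meta = meta.set_index("sample_id")
    _validate_ontology(meta)
    return meta


def write_sample_metadata(meta: pd.DataFrame, path, sep: str = "\t") -> None:
    out = meta.copy()
    out.insert(0, "sample_id", out.index.to_numpy())
    out.to_csv(path, sep=sep, index=False)


def load_panels(path) -> dict[str, GenePanel]:
    """Load gene panels from a YAML/JSON mapping name -> list of symbols."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: expected a mapping of panel name to genes")
    return {name: GenePanel(name, tuple(genes)) for name, genes in raw.items()}


# ----------------------------------------------------------------------
# Panel resolution
# ----------------------------------------------------------------------

def resolve_panel(table: ExpressionTable, panel: GenePanel,
                  policy: str = "strict") -> dict[str, list[str]]:
    """Map each panel gene to its feature ids in *table*.

    ``strict`` raises :class:`MissingGeneError` unless every panel gene has
    at least one feature; ``subset`` returns the present genes and logs the
    missing ones.  The result preserves panel gene order and, per gene,
    the table's feature order — resolution is idempotent and independent
    of the order in which panels are resolved.
    """
    if policy not in ("strict", "subset"):
        raise ValidationError(f"unknown policy {policy!r}")
    gene_map = table.gene_map
    out: dict[str, list[str]] = {}
    missing: list[str] = []
    for gene in panel.genes:
        feats = list(gene_map.index[gene_map == gene])
        if feats:
            out[gene] = feats
        else:
            missing.append(gene)
    if missing:
        if policy == "strict":
            raise MissingGeneError(panel.name, missing)
        logger.warning("panel %s: genes absent from table: %s",
                       panel.name, ", ".join(missing))
    return out


def panel_feature_ids(resolution: dict[str, list[str]]) -> list[str]:
    """Flatten a panel resolution to a feature-id list."""
    return [f for feats in resolution.values() for f in feats]
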