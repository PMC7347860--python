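"""Synthetic expression datasets with recorded ground truth.

Three generators emulate the statistical structure the analysis pipeline
assumes, so every downstream stage has a self-contained test bed:

* :func:`gen_regional_microarray` — a log2 microarray-like table of probe
  intensities over subjects x brain substructures, with collinear probes
  per gene (single-factor model), ontogeny-driven region clusters, linear
  age effects, and additive per-subject offsets.
* :func:`gen_single_cell` — a linear-scale (uTPM-like) single-cell table
  whose per-cell AMPAR/GABA_A_R expression sums are constructed so that
  the tE/I ratio of each cell type has a configured mean and dispersion.
* :func:`gen_developmental` — a linear-scale (RPKM-like) developmental
  series with stable total AMPAR expression, logistically rising GABA_A_R
  expression (so tE/I falls to a plateau), rising KCC2 and declining
  NKCC1.

Every generator is a pure function of its config (which carries the seed);
identical configs give bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from tei.core_io import (
    AMPAR_GENES,
    ExpressionTable,
    ValidationError,
)

__all__ = [
    "RegionalSimConfig",
    "CellTypeSpec",
    "CellSimConfig",
    "DevSimConfig",
    "GroundTruth",
    "default_regional_config",
    "default_cell_config",
    "default_dev_config",
    "gen_regional_microarray",
    "gen_single_cell",
    "gen_developmental",
]


@dataclass
class GroundTruth:
    """Planted parameters recorded alongside a generated table."""

    profiles: dict | None = None            # gene -> {substructure: mean log2}
    representative_probe: dict | None = None  # gene -> probe id with max loading
    loadings: dict | None = None            # gene -> {probe id: lambda}
    partition: dict | None = None           # substructure -> cluster label
    beta_age: dict | None = None            # gene -> log2 units / year
    group_tei: dict | None = None           # group label -> true mean tE/I
    group_dispersion: dict | None = None    # group label -> tE/I CV
    age_grid: np.ndarray | None = None
    true_tei: np.ndarray | None = None      # tE/I on age_grid (noise-free)
    tei_plateau: float | None = None
    kcc2_nkcc1: np.ndarray | None = None    # true transporter ratio on grid

    def to_jsonable(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if v is None:
                continue
            if isinstance(v, np.ndarray):
                v = v.tolist()
            out[k] = v
        return out


# ----------------------------------------------------------------------
# Regional microarray
# ----------------------------------------------------------------------

@dataclass
class RegionalSimConfig:
    """Configuration for the microarray-like regional generator.

    ``regions`` lists (region, structure, substructure, ontogeny) tuples;
    ``profiles`` gives the true mean log2 expression of each gene in each
    substructure; ``probe_plan`` gives per-gene probe loadings λ in (0, 1].
    Probe j of gene g in sample s is

        λ_j · F_gs + sqrt(1 − λ_j²) · ε + β_age · age_s,   ε ~ N(0, σ)

    where F_gs is the substructure profile plus an additive per-subject,
    per-gene offset (SD ``subject_sd``) shared across regions.
    """

    regions: tuple  # of (region, structure, substructure, ontogeny)
    profiles: dict  # gene -> {substructure: mean log2}
    probe_plan: dict  # gene -> tuple of loadings in (0, 1]
    n_subjects: int = 6
    age_range: tuple = (24.0, 57.0)
    beta_age: dict = field(default_factory=dict)  # gene -> log2/year
    sigma: float = 0.6
    subject_sd: float = 0.25
    seed: int = 0

    def validate(self):
        if not self.regions:
            raise ValidationError("no regions configured")
        if self.n_subjects < 2:
            raise ValidationError("need at least 2 subjects")
        if self.sigma < 0 or self.subject_sd < 0:
            raise ValidationError("noise SDs must be non-negative")
        subs = [r[2] for r in self.regions]
        if len(set(subs)) != len(subs):
            raise ValidationError("duplicate substructures")
        for gene, lams in self.probe_plan.items():
            if not lams:
                raise ValidationError(f"gene {gene}: empty probe plan")
            if any(not (0 < l <= 1) for l in lams):
                raise ValidationError(f"gene {gene}: loadings must be in (0, 1]")
            if gene not in self.profiles:
                raise ValidationError(f"gene {gene}: no profile")
            for _, _, sub, _ in self.regions:
                if sub not in self.profiles[gene]:
                    raise ValidationError(f"gene {gene}: no profile for {sub}")


# Default ontogeny-level mean log2 profiles.  Telencephalic structures are
# GRIA2-high; metencephalic ones are GRIA3-low with high GRIA2/GRIA4 —
# the axis along which real brain structures separate.
_DEFAULT_ONTOGENY_MEANS = {
    "GRIA1": {"telencephalic": 9.5, "metencephalic": 6.0},
    "GRIA2": {"telencephalic": 10.5, "metencephalic": 9.2},
    "GRIA3": {"telencephalic": 9.0, "metencephalic": 3.8},
    "GRIA4": {"telencephalic": 9.8, "metencephalic": 10.3},
    "GABRA1": {"telencephalic": 10.2, "metencephalic": 10.8},
    "GABRB2": {"telencephalic": 10.0, "metencephalic": 9.6},
    "GABRG2": {"telencephalic": 9.7, "metencephalic": 9.4},
}

_DEFAULT_PROBE_PLAN = {
    "GRIA1": (0.95, 0.85, 0.70, 0.55),
    "GRIA2": (0.95, 0.85, 0.70, 0.55),
    "GRIA3": (0.95, 0.85, 0.70, 0.55),
    "GRIA4": (0.95, 0.85, 0.70, 0.55, 0.40),
    "GABRA1": (0.90, 0.70),
    "GABRB2": (0.90, 0.70),
    "GABRG2": (0.90, 0.70),
}


def default_regional_config(seed: int = 0, n_subjects: int = 6,
                            sigma: float = 0.6, subject_sd: float = 0.25,
                            beta_age: dict | None = None,
                            substructure_jitter: float = 0.3) -> RegionalSimConfig:
    """Two-ontogeny, 20-substructure default configuration.

    Ten telencephalic substructures (frontal lobe + hippocampal formation)
    and ten metencephalic ones (cerebellar cortex + basal pons).  Per-
    substructure profiles are the ontogeny means plus a seeded jitter so
    substructures are distinct but cluster by ontogeny.  The 17-probe
    AMPAR plan (4 probes each for GRIA1-3, 5 for GRIA4) mirrors the
    microarray design; three GABA_A_R genes are included so the tE/I
    stage runs end to end.
    """
    regions = []
    for i in range(5):
        regions.append(("Cerebral cortex", "FL", f"FL_{i + 1}", "telencephalic"))
    for sub in ("CA1", "CA2", "CA3", "CA4", "DG"):
        regions.append(("Cerebral cortex", "HiF", sub, "telencephalic"))
    for i in range(5):
        regions.append(("Metencephalon", "CbCx", f"Cb_{i + 1}", "metencephalic"))
    for i in range(5):
        regions.append(("Metencephalon", "Bpons", f"Bp_{i + 1}", "metencephalic"))

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11E]))
    profiles: dict[str, dict[str, float]] = {}
    for gene, means in _DEFAULT_ONTOGENY_MEANS.items():
        profiles[gene] = {
            sub: means[onto] + rng.normal(0.0, substructure_jitter)
            for _, _, sub, onto in regions
        }
    return RegionalSimConfig(
        regions=tuple(regions),
        profiles=profiles,
        probe_plan=dict(_DEFAULT_PROBE_PLAN),
        n_subjects=n_subjects,
        beta_age=dict(beta_age or {}),
        sigma=sigma,
        subject_sd=subject_sd,
        seed=seed,
    )


def gen_regional_microarray(cfg: RegionalSimConfig):
    """Generate (ExpressionTable[log2], sample metadata, GroundTruth)."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5EED]))

    genes = list(cfg.probe_plan)
    subjects = [f"S{i + 1:02d}" for i in range(cfg.n_subjects)]
    ages = rng.uniform(*cfg.age_range, size=cfg.n_subjects)
    sexes = ["M" if i % 6 != 5 else "F" for i in range(cfg.n_subjects)]

    # per-subject, per-gene additive offset shared across regions
    subj_offsets = rng.normal(0.0, cfg.subject_sd,
                              size=(cfg.n_subjects, len(genes)))

    rows = []
    meta_rows = []
    probe_ids: list[str] = []
    feature_gene: list[str] = []
    for gi, gene in enumerate(genes):
        for j, lam in enumerate(cfg.probe_plan[gene]):
            probe_ids.append(f"{gene}_p{j + 1}")
            feature_gene.append(gene)

    data = np.empty((cfg.n_subjects * len(cfg.regions), len(probe_ids)))
    sidx = 0
    for si, subj in enumerate(subjects):
        for region, structure, sub, onto in cfg.regions:
            col = 0
            for gi, gene in enumerate(genes):
                f_gs = cfg.profiles[gene][sub] + subj_offsets[si, gi]
                beta = cfg.beta_age.get(gene, 0.0)
                for lam in cfg.probe_plan[gene]:
                    eps = rng.normal(0.0, cfg.sigma) if cfg.sigma > 0 else 0.0
                    data[sidx, col] = (lam * f_gs
                                       + np.sqrt(1.0 - lam ** 2) * eps
                                       + beta * ages[si])
                    col += 1
            meta_rows.append({
                "sample_id": f"{subj}|{sub}",
                "subject_id": subj,
                "age": ages[si],
                "sex": sexes[si],
                "region": region,
                "structure": structure,
                "substructure": sub,
            })
            sidx += 1

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    values = pd.DataFrame(data, index=meta.index, columns=probe_ids)
    feature_meta = pd.DataFrame({"gene_symbol": feature_gene},
                                index=pd.Index(probe_ids, name="feature_id"))
    table = ExpressionTable(values, "log2", feature_meta, meta)

    truth = GroundTruth(
        profiles={g: dict(p) for g, p in cfg.profiles.items()},
        representative_probe={
            g: f"{g}_p{int(np.argmax(cfg.probe_plan[g])) + 1}" for g in genes
        },
        loadings={
            g: {f"{g}_p{j + 1}": lam for j, lam in enumerate(cfg.probe_plan[g])}
            for g in genes
        },
        partition={sub: onto for _, _, sub, onto in cfg.regions},
        beta_age={g: cfg.beta_age.get(g, 0.0) for g in genes},
    )
    return table, meta, truth


# ----------------------------------------------------------------------
# Single cell
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CellTypeSpec:
    """One cell type: size, target mean tE/I, and tE/I dispersion (CV)."""

    name: str
    n_cells: int
    mu_tei: float
    dispersion: float  # coefficient of variation of the per-cell tE/I

    def __post_init__(self):
        if self.mu_tei <= 0:
            raise ValidationError(f"{self.name}: mu_tei must be > 0")
        if self.n_cells < 2:
            raise ValidationError(f"{self.name}: need n_cells >= 2")
        if self.dispersion < 0:
            raise ValidationError(f"{self.name}: dispersion must be >= 0")


# The seven interneuron types with their published per-type mean tE/I
# (mean of per-cell ΣAMPAR/ΣGABA_A_R) and cell counts; dispersion is the
# printed SD over the mean.
_DEFAULT_CELL_TYPES = (
    CellTypeSpec("CCKC", 64, 0.66, 0.13 / 0.66),
    CellTypeSpec("CHC1", 80, 1.7, 0.38 / 1.7),
    CellTypeSpec("CHC2", 52, 1.0, 0.43 / 1.0),
    CellTypeSpec("ISC", 63, 0.80, 0.26 / 0.80),
    CellTypeSpec("LPC", 136, 1.1, 0.22 / 1.1),
    CellTypeSpec("MNC", 62, 10.0, 6.3 / 10.0),
    CellTypeSpec("PVBC", 127, 0.96, 0.13 / 0.96),
)

_SC_GABAAR_GENES = ("GABRA1", "GABRA2", "GABRB1", "GABRB2", "GABRB3",
                    "GABRG2", "GABRD")


@dataclass
class CellSimConfig:
    """Configuration for the single-cell (uTPM-like) generator."""

    cell_types: tuple = _DEFAULT_CELL_TYPES
    gabaar_total_mean: float = 300.0  # uTPM summed over GABA_A_R genes
    gabaar_total_cv: float = 0.3
    share_concentration: float = 80.0  # Dirichlet concentration of gene shares
    zero_inflation: float = 0.0
    seed: int = 0

    def validate(self):
        if not self.cell_types:
            raise ValidationError("no cell types configured")
        for spec in self.cell_types:
            pass  # specs validate themselves on construction
        if not (0 <= self.zero_inflation < 1):
            raise ValidationError("zero_inflation must be in [0, 1)")
        if self.gabaar_total_mean <= 0:
            raise ValidationError("gabaar_total_mean must be > 0")


def default_cell_config(seed: int = 0, n_cells: int | None = None) -> CellSimConfig:
    """Default seven-type configuration; *n_cells* overrides every type's size."""
    types = _DEFAULT_CELL_TYPES
    if n_cells is not None:
        types = tuple(replace(t, n_cells=n_cells) for t in types)
    return CellSimConfig(cell_types=types, seed=seed)


def _lognormal_mean_cv(rng, mean, cv, size):
    """Lognormal draws with the given mean and coefficient of variation."""
    if cv == 0:
        return np.full(size, float(mean))
    s2 = np.log1p(cv ** 2)
    return np.exp(rng.normal(np.log(mean) - s2 / 2.0, np.sqrt(s2), size=size))


def gen_single_cell(cfg: CellSimConfig):
    """Generate (ExpressionTable[linear], sample metadata, GroundTruth).

    Per cell, a tE/I ratio is drawn lognormal around the type's target
    mean with the configured CV; the total GABA_A_R sum is drawn
    lognormal, the AMPAR sum is ratio x total, and each sum is split
    across its panel genes by a Dirichlet draw — so the per-cell ratio is
    controlled exactly and dispersion 0 gives tE/I == mu exactly.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xCE11]))
    ampar = list(AMPAR_GENES)
    gabaar = list(_SC_GABAAR_GENES)
    genes = ampar + gabaar

    a_base = np.array([0.20, 0.40, 0.15, 0.25])
    g_base = np.full(len(gabaar), 1.0 / len(gabaar))

    rows, meta_rows = [], []
    for spec in cfg.cell_types:
        tei = _lognormal_mean_cv(rng, spec.mu_tei, spec.dispersion, spec.n_cells)
        g_tot = _lognormal_mean_cv(rng, cfg.gabaar_total_mean,
                                   cfg.gabaar_total_cv, spec.n_cells)
        a_tot = tei * g_tot
        a_shares = rng.dirichlet(cfg.share_concentration * a_base, spec.n_cells)
        g_shares = rng.dirichlet(cfg.share_concentration * g_base, spec.n_cells)
        vals = np.hstack([a_shares * a_tot[:, None], g_shares * g_tot[:, None]])
        if cfg.zero_inflation > 0:
            vals[rng.random(vals.shape) < cfg.zero_inflation] = 0.0
        rows.append(vals)
        meta_rows.extend(
            {"sample_id": f"{spec.name}_{i + 1:04d}", "cell_type": spec.name}
            for i in range(spec.n_cells)
        )

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    values = pd.DataFrame(np.vstack(rows), index=meta.index, columns=genes)
    table = ExpressionTable(values, "linear", None, meta)
    truth = GroundTruth(
        group_tei={t.name: t.mu_tei for t in cfg.cell_types},
        group_dispersion={t.name: t.dispersion for t in cfg.cell_types},
    )
    return table, meta, truth


# ----------------------------------------------------------------------
# Development
# ----------------------------------------------------------------------

@dataclass
class DevSimConfig:
    """Configuration for the developmental (RPKM-like) generator.

    Ages are in years with birth at 0 (prenatal negative, converted from
    post-conception weeks as (pcw - 40) / 52).  Total AMPAR expression is
    a constant ``ampar_level``; total GABA_A_R expression follows a
    rising logistic, so the true tE/I falls from ampar_level/floor
    prenatally to ampar_level/ceiling — the adult plateau.  ``noise_sd``
    is the SD of a multiplicative lognormal factor (log scale), so
    generated linear values stay positive and noise 0 is exact.
    """

    ages: tuple = ()
    subjects_per_age: int = 2
    regions: tuple = ("DFC", "VFC", "MFC", "STC", "ITC", "A1C")
    ampar_level: float = 100.0
    gabaar_floor: float = 80.0
    gabaar_ceiling: float = 100.0 / 0.31
    gabaar_midpoint: float = -0.1  # years
    gabaar_rate: float = 12.0      # 1 / years
    kcc2_floor: float = 4.0
    kcc2_ceiling: float = 90.0
    kcc2_midpoint: float = -0.05
    kcc2_rate: float = 10.0
    nkcc1_high: float = 60.0
    nkcc1_low: float = 15.0
    nkcc1_midpoint: float = -0.05
    nkcc1_rate: float = 10.0
    nkcc2_level: float = 0.5
    noise_sd: float = 0.08
    seed: int = 0

    def validate(self):
        if self.gabaar_ceiling <= self.gabaar_floor or self.gabaar_floor <= 0:
            raise ValidationError("need gabaar ceiling > floor > 0")
        if self.gabaar_rate <= 0:
            raise ValidationError("gabaar rate must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if len(self.ages) < 2:
            raise ValidationError("need at least 2 ages")


_DEFAULT_PCW = (12, 16, 19, 21, 24, 26, 35, 37)
_DEFAULT_POSTNATAL = (0.33, 0.5, 1.0, 2.0, 4.0, 8.0, 13.0, 18.0, 21.0,
                      30.0, 36.0, 40.0)


def pcw_to_years(pcw: float) -> float:
    """Post-conception weeks to years relative to birth at 40 pcw."""
    return (pcw - 40.0) / 52.0


def default_dev_config(seed: int = 0) -> DevSimConfig:
    ages = tuple(pcw_to_years(w) for w in _DEFAULT_PCW) + _DEFAULT_POSTNATAL
    return DevSimConfig(ages=ages, seed=seed)


def _logistic(t, lo, hi, mid, rate):
    return lo + (hi - lo) / (1.0 + np.exp(-rate * (np.asarray(t, float) - mid)))


def gen_developmental(cfg: DevSimConfig):
    """Generate (ExpressionTable[linear], sample metadata, GroundTruth)."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xDEA1]))

    ampar = list(AMPAR_GENES)
    gabaar = ["GABRA1", "GABRA2", "GABRB2", "GABRG2", "GABRD"]
    transporters = ["SLC12A5", "SLC12A2", "SLC12A1"]
    genes = ampar + gabaar + transporters
    a_shares = np.array([0.20, 0.40, 0.15, 0.25])
    g_shares = np.full(len(gabaar), 1.0 / len(gabaar))

    rows, meta_rows = [], []
    subj = 0
    for age in cfg.ages:
        for _ in range(cfg.subjects_per_age):
            subj += 1
            subj_id = f"D{subj:03d}"
            for region in cfg.regions:
                g_tot = _logistic(age, cfg.gabaar_floor, cfg.gabaar_ceiling,
                                  cfg.gabaar_midpoint, cfg.gabaar_rate)
                kcc2 = _logistic(age, cfg.kcc2_floor, cfg.kcc2_ceiling,
                                 cfg.kcc2_midpoint, cfg.kcc2_rate)
                nkcc1 = _logistic(age, cfg.nkcc1_high, cfg.nkcc1_low,
                                  cfg.nkcc1_midpoint, cfg.nkcc1_rate)
                base = np.concatenate([
                    cfg.ampar_level * a_shares,
                    g_tot * g_shares,
                    [kcc2, nkcc1, cfg.nkcc2_level],
                ])
                if cfg.noise_sd > 0:
                    base = base * np.exp(
                        rng.normal(0.0, cfg.noise_sd, size=base.shape))
                rows.append(base)
                meta_rows.append({
                    "sample_id": f"{subj_id}|{region}",
                    "subject_id": subj_id,
                    "age": age,
                    "region": "cortex",
                    "structure": region,
                })

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    values = pd.DataFrame(np.vstack(rows), index=meta.index, columns=genes)
    table = ExpressionTable(values, "linear", None, meta)

    grid = np.asarray(sorted(set(cfg.ages)), float)
    g_curve = _logistic(grid, cfg.gabaar_floor, cfg.gabaar_ceiling,
                        cfg.gabaar_midpoint, cfg.gabaar_rate)
    truth = GroundTruth(
        age_grid=grid,
        true_tei=cfg.ampar_level / g_curve,
        tei_plateau=cfg.ampar_level / cfg.gabaar_ceiling,
        kcc2_nkcc1=(_logistic(grid, cfg.kcc2_floor, cfg.kcc2_ceiling,
                              cfg.kcc2_midpoint, cfg.kcc2_rate)
                    / _logistic(grid, cfg.nkcc1_high, cfg.nkcc1_low,
                                cfg.nkcc1_midpoint, cfg.nkcc1_rate)),
    )
    return table, meta, truth
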