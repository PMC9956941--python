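"""Synthetic paired microbiome / physiochemistry / metabolome data.

Real cohorts of naturally aged rice wine (huangjiu) pair three measurement
layers on the same jars: a handful of physiochemical indexes (total acid,
amino nitrogen, reducing sugar, pH, conductivity), a compositional bacterial
community profiled from the wine lees, and a targeted metabolite panel.
No public deposit of such a cohort exists, so this module generates one with
the same statistical structure — ~110 samples at discrete aging years, a
community dominated by a single genus (~59% mean relative abundance), taxa
whose abundance tracks aging year or total acid, and metabolites driven by
aging year, by taxa, by indexes, or by nothing at all — together with a
machine-readable record of every planted effect, so that the downstream
prediction and attribution stages can be tested for recovery of known truth.

All randomness flows from a single seed fanned out to per-stage child
streams, so a dataset is reproducible bit-for-bit from its config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "PlantedEffect",
    "SimConfig",
    "GroundTruth",
    "StudyTables",
    "generate_dataset",
    "inject_missingness",
    "default_effect_table",
]

PHYSIO_INDEXES = ("total_acid", "amino_nitrogen", "reducing_sugar", "pH", "conductivity")

#: fixed offsets for per-stage child seeds (reproducibility with stage independence)
_STAGE = {"metadata": 0, "physio": 1, "taxa": 2, "counts": 3, "metabolites": 4, "censor": 5}


@dataclass(frozen=True)
class PlantedEffect:
    """One planted driver→metabolite association.

    source is ``"aging_year"``, ``"taxon:<species_id>"`` or ``"index:<name>"``;
    form is one of ``linear``, ``saturating`` (x/(1+|x|)), ``threshold``
    (indicator above the median) or ``interaction`` (product with a second
    source, given in ``source2``). The coefficient is on the standardized
    scale and must be nonzero.
    """

    target: str
    source: str
    form: str = "linear"
    coefficient: float = 1.0
    source2: str | None = None

    def __post_init__(self) -> None:
        if self.coefficient == 0:
            raise ValueError(f"planted effect on {self.target}: coefficient must be nonzero")
        if self.form not in ("linear", "saturating", "threshold", "interaction"):
            raise ValueError(f"unknown effect form {self.form!r}")
        if self.form == "interaction" and self.source2 is None:
            raise ValueError("interaction effects need a second source")

    @property
    def sign(self) -> int:
        return 1 if self.coefficient > 0 else -1


def default_effect_table(n_metabolites: int | None = None) -> list[PlantedEffect]:
    """Default planted effects: a mix of year-, index- and taxon-driven
    metabolites across all functional forms, plus implicit pure-noise
    metabolites (any metabolite without an entry here is noise).

    With ``n_metabolites`` given, effects targeting metabolites outside the
    panel m01..m<n> are dropped, so small panels stay valid.
    """
    E = PlantedEffect
    table = [
        E("m01", "aging_year", "linear", +1.0),
        E("m02", "aging_year", "linear", -0.8),
        E("m03", "aging_year", "saturating", +1.0),
        E("m04", "aging_year", "threshold", +0.8),
        E("m05", "index:total_acid", "linear", +1.0),
        E("m06", "index:total_acid", "linear", -0.8),
        E("m07", "index:pH", "linear", +0.7),
        E("m08", "taxon:sp002", "linear", +1.0),
        E("m09", "taxon:sp001", "linear", -0.8),
        E("m10", "taxon:sp003", "linear", +0.9),
        E("m11", "taxon:sp004", "saturating", +0.8),
        E("m12", "taxon:sp005", "threshold", +0.7),
        E("m13", "aging_year", "interaction", +0.8, source2="taxon:sp002"),
        E("m14", "aging_year", "linear", +0.6),
        E("m14", "taxon:sp006", "linear", +0.6),
        E("m15", "index:reducing_sugar", "linear", -0.7),
        E("m16", "taxon:sp006", "linear", +0.5),
    ]
    if n_metabolites is not None:
        panel = {f"m{i + 1:02d}" for i in range(n_metabolites)}
        table = [e for e in table if e.target in panel]
    return table


@dataclass
class SimConfig:
    """Configuration of one synthetic cohort.

    Defaults mirror the study design this generator emulates: 110 jars at
    aging years {3, 8, 10, 20, 25}, one dominant taxon near 59% mean
    relative abundance, and a sparse species table aggregated to genus via a
    taxonomy map.
    """

    n_samples: int = 110
    aging_years: tuple[int, ...] = (3, 8, 10, 20, 25)
    aging_year_weights: tuple[float, ...] | None = None  # uniform if None
    n_taxa_species: int = 60
    n_taxa_genus: int = 25
    dominant_taxon_mean_fraction: float = 0.59
    n_metabolites: int = 24
    effect_table: list[PlantedEffect] = field(default_factory=default_effect_table)
    noise_sd: float = 0.5
    censor_quantile: float = 0.05
    detection_floor: float = 1e-4
    sequencing_depth: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aging_year_weights is not None:
            w = np.asarray(self.aging_year_weights, float)
            if len(w) != len(self.aging_years) or np.any(w <= 0):
                raise ValueError("aging_year_weights must be positive, one per aging year")
        if not 0 < self.dominant_taxon_mean_fraction < 1:
            raise ValueError("dominant_taxon_mean_fraction must lie in (0, 1)")
        if not 0 <= self.censor_quantile < 1:
            raise ValueError("censor_quantile must lie in [0, 1)")
        if self.n_taxa_species < 6 or self.n_taxa_genus < 2:
            raise ValueError("need at least 6 species and 2 genera")
        if self.n_taxa_genus > self.n_taxa_species:
            raise ValueError("cannot have more genera than species")
        targets = {e.target for e in self.effect_table}
        if self.n_metabolites < len(targets):
            raise ValueError(
                f"n_metabolites={self.n_metabolites} < {len(targets)} distinct effect targets"
            )
        known = {f"sp{i + 1:03d}" for i in range(self.n_taxa_species)}
        for e in self.effect_table:
            for src in filter(None, (e.source, e.source2)):
                if src.startswith("taxon:") and src.split(":", 1)[1] not in known:
                    raise ValueError(f"effect on {e.target} references unknown {src}")
                if src.startswith("index:") and src.split(":", 1)[1] not in PHYSIO_INDEXES:
                    raise ValueError(f"effect on {e.target} references unknown {src}")

    def stage_rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STAGE[stage],))
        )


@dataclass
class GroundTruth:
    """The planted effects of one generated dataset, for recovery testing."""

    effects: list[PlantedEffect]
    noise_metabolites: list[str]

    def effects_for(self, metabolite: str) -> list[PlantedEffect]:
        return [e for e in self.effects if e.target == metabolite]

    def planted_sign(self, metabolite: str, source: str) -> int:
        for e in self.effects:
            if e.target == metabolite and source in (e.source, e.source2):
                return e.sign
        return 0

    def to_dict(self) -> dict:
        return {
            "effects": [asdict(e) for e in self.effects],
            "noise_metabolites": list(self.noise_metabolites),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            effects=[PlantedEffect(**e) for e in d["effects"]],
            noise_metabolites=list(d["noise_metabolites"]),
        )


@dataclass
class StudyTables:
    """Aligned sample × variable tables for one cohort.

    All tables are indexed by the same ordered sample IDs. Taxa tables are
    species-level; genus-level views are obtained by summing species within
    a genus using the ``taxonomy`` map.
    """

    metadata: pd.DataFrame        # columns: aging_year
    physio: pd.DataFrame          # the five physiochemical indexes
    metabolites: pd.DataFrame     # nonnegative concentrations, NaN allowed
    taxa_relabund: pd.DataFrame   # species-level, rows on the simplex
    taxa_counts: pd.DataFrame     # species-level integer counts
    taxonomy: pd.Series           # species id -> genus id

    def __post_init__(self) -> None:
        idx = self.metadata.index
        for name in ("physio", "metabolites", "taxa_relabund", "taxa_counts"):
            other = getattr(self, name).index
            if not idx.equals(other):
                missing = sorted(set(idx).symmetric_difference(other))
                raise ValueError(f"sample IDs of {name} disagree with metadata: {missing}")
        missing_tax = set(self.taxa_relabund.columns) - set(self.taxonomy.index)
        if missing_tax:
            raise ValueError(f"taxa missing from taxonomy map: {sorted(missing_tax)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.metadata.index

    @property
    def aging_year(self) -> pd.Series:
        return self.metadata["aging_year"]

    def genus_relabund(self) -> pd.DataFrame:
        g = self.taxa_relabund.T.groupby(self.taxonomy).sum().T
        g.columns.name = None
        return g

    def genus_counts(self) -> pd.DataFrame:
        g = self.taxa_counts.T.groupby(self.taxonomy).sum().T
        g.columns.name = None
        return g


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def _species_log_mean(cfg: SimConfig) -> np.ndarray:
    """Log-scale mean abundance per species: geometric rank-abundance decay
    for the tail, dominant species calibrated so its expected share matches
    the configured fraction."""
    n = cfg.n_taxa_species
    mu = np.empty(n)
    # tail: exp(-0.25 * rank) rank-abundance curve
    tail_w = np.exp(-0.25 * np.arange(1, n))
    sigma_tail = 0.8
    tail_mean = tail_w * math.exp(sigma_tail**2 / 2)
    f = cfg.dominant_taxon_mean_fraction
    sigma_dom = 0.25
    dom_mean = f / (1 - f) * tail_mean.sum()
    # renormalizing to the simplex shrinks the dominant share below the
    # ratio of means (Jensen); 1.13 corrects the bias at these noise scales
    mu[0] = math.log(1.13 * dom_mean) - sigma_dom**2 / 2
    mu[1:] = np.log(tail_w)
    return mu


def _generate_taxa(cfg: SimConfig, z_age: np.ndarray, z_acid: np.ndarray) -> pd.DataFrame:
    """Species relative abundances: log-normal base with one dominant taxon,
    one taxon monotone-up in aging year (sp002), one monotone-up in total
    acid (sp003) and one monotone-down in aging year (sp004)."""
    rng = cfg.stage_rng("taxa")
    n, p = cfg.n_samples, cfg.n_taxa_species
    mu = _species_log_mean(cfg)
    sigma = np.full(p, 0.8)
    sigma[0] = 0.25
    log_a = mu + sigma * rng.standard_normal((n, p))
    log_a[:, 1] += 0.9 * z_age
    log_a[:, 2] += 0.9 * z_acid
    log_a[:, 3] -= 0.6 * z_age
    a = np.exp(log_a)
    rel = a / a.sum(axis=1, keepdims=True)
    return pd.DataFrame(rel, columns=[f"sp{i + 1:03d}" for i in range(p)])


def _apply_detection_floor(rel: pd.DataFrame, floor: float) -> pd.DataFrame:
    """Zero out sub-detection abundances and renormalize rows to the simplex;
    creates the structural zeros that exercise CLR zero replacement."""
    x = rel.to_numpy(copy=True)
    x[x < floor] = 0.0
    rowsum = x.sum(axis=1, keepdims=True)
    if np.any(rowsum == 0):
        raise ValueError("detection floor removed every taxon in at least one sample")
    return pd.DataFrame(x / rowsum, index=rel.index, columns=rel.columns)


def _source_vector(
    source: str, z_age: np.ndarray, physio: pd.DataFrame, clr_species: pd.DataFrame
) -> np.ndarray:
    if source == "aging_year":
        return z_age
    kind, _, name = source.partition(":")
    if kind == "index":
        return _standardize(physio[name].to_numpy())
    if kind == "taxon":
        return _standardize(clr_species[name].to_numpy())
    raise ValueError(f"unknown effect source {source!r}")


def _apply_form(effect: PlantedEffect, x: np.ndarray, x2: np.ndarray | None) -> np.ndarray:
    if effect.form == "linear":
        return x
    if effect.form == "saturating":
        return x / (1.0 + np.abs(x))
    if effect.form == "threshold":
        return (x > np.median(x)).astype(float)
    if effect.form == "interaction":
        assert x2 is not None
        return x * x2
    raise AssertionError(effect.form)


def generate_dataset(cfg: SimConfig) -> tuple[StudyTables, GroundTruth]:
    """Generate one cohort plus its ground truth.

    Metabolite m with planted effects e_1..e_k is built as the empirical
    standardization of sum_j coef_j * g_j(standardized source_j) plus
    N(0, noise_sd²) noise, exponentiated to a positive concentration;
    metabolites with no planted effect are exponentiated pure noise.
    Censoring below the configured quantile is then applied per metabolite.
    """
    sample_ids = pd.Index([f"S{i + 1:03d}" for i in range(cfg.n_samples)], name="sample_id")

    rng_meta = cfg.stage_rng("metadata")
    weights = cfg.aging_year_weights
    p = None if weights is None else np.asarray(weights, float) / np.sum(weights)
    years = rng_meta.choice(np.asarray(cfg.aging_years), size=cfg.n_samples, p=p)
    metadata = pd.DataFrame({"aging_year": years}, index=sample_ids)
    z_age = _standardize(years.astype(float))

    # physiochemical indexes: total acid rises with age; pH falls with acid
    rng_p = cfg.stage_rng("physio")
    total_acid = 5.0 + 0.8 * z_age + 0.5 * rng_p.standard_normal(cfg.n_samples)
    z_acid = _standardize(total_acid)
    physio = pd.DataFrame(
        {
            "total_acid": total_acid,
            "amino_nitrogen": 0.60 + 0.10 * z_age + 0.08 * rng_p.standard_normal(cfg.n_samples),
            "reducing_sugar": 15.0 - 1.0 * z_age + 1.5 * rng_p.standard_normal(cfg.n_samples),
            "pH": 4.0 - 0.25 * z_acid + 0.10 * rng_p.standard_normal(cfg.n_samples),
            "conductivity": 2000.0 + 150.0 * z_acid + 100.0 * rng_p.standard_normal(cfg.n_samples),
        },
        index=sample_ids,
    )

    rel = _generate_taxa(cfg, z_age, z_acid)
    rel.index = sample_ids
    # clr on the pre-floor composition: the noiseless driver signal
    log_rel = np.log(rel.to_numpy())
    clr = pd.DataFrame(
        log_rel - log_rel.mean(axis=1, keepdims=True), index=sample_ids, columns=rel.columns
    )
    rel = _apply_detection_floor(rel, cfg.detection_floor)

    rng_c = cfg.stage_rng("counts")
    counts = np.vstack(
        [rng_c.multinomial(cfg.sequencing_depth, row) for row in rel.to_numpy()]
    )
    taxa_counts = pd.DataFrame(counts, index=sample_ids, columns=rel.columns)

    species = list(rel.columns)
    genus_of = pd.Series(
        [f"g{(i % cfg.n_taxa_genus) + 1:02d}" for i in range(len(species))],
        index=pd.Index(species, name="species"),
        name="genus",
    )

    rng_m = cfg.stage_rng("metabolites")
    met_names = [f"m{i + 1:02d}" for i in range(cfg.n_metabolites)]
    targets = {e.target for e in cfg.effect_table}
    unknown = targets - set(met_names)
    if unknown:
        raise ValueError(f"effect targets outside the metabolite panel: {sorted(unknown)}")
    cols = {}
    for name in met_names:
        effects = [e for e in cfg.effect_table if e.target == name]
        signal = np.zeros(cfg.n_samples)
        for e in effects:
            x = _source_vector(e.source, z_age, physio, clr)
            x2 = (
                _source_vector(e.source2, z_age, physio, clr) if e.source2 is not None else None
            )
            signal = signal + e.coefficient * _apply_form(e, x, x2)
        u = signal + cfg.noise_sd * rng_m.standard_normal(cfg.n_samples)
        if not effects:
            u = rng_m.standard_normal(cfg.n_samples)
        cols[name] = np.exp(_standardize(u))
    metabolites = pd.DataFrame(cols, index=sample_ids)
    if cfg.censor_quantile > 0:
        metabolites = inject_missingness(metabolites, cfg.censor_quantile)

    tables = StudyTables(
        metadata=metadata,
        physio=physio,
        metabolites=metabolites,
        taxa_relabund=rel,
        taxa_counts=taxa_counts,
        taxonomy=genus_of,
    )
    truth = GroundTruth(
        effects=list(cfg.effect_table),
        noise_metabolites=[n for n in met_names if n not in targets],
    )
    return tables, truth


def inject_missingness(metabolites: pd.DataFrame, censor_quantile: float) -> pd.DataFrame:
    """Censor low values: per metabolite, the lowest ``censor_quantile``
    fraction of the non-missing values becomes NaN (ties broken by sample
    position, earlier samples censored first). A metabolite is never fully
    censored because the quantile is < 1.
    """
    if not 0 <= censor_quantile < 1:
        raise ValueError("censor_quantile must lie in [0, 1)")
    if censor_quantile == 0:
        return metabolites.copy()
    out = metabolites.copy()
    for col in out.columns:
        v = out[col]
        obs = v.dropna()
        k = int(math.floor(censor_quantile * len(obs)))
        if k == 0:
            continue
        # stable sort on value; positional order breaks ties
        order = np.argsort(obs.to_numpy(), kind="stable")
        out.loc[obs.index[order[:k]], col] = np.nan
    return out
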