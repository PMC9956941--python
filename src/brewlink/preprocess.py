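"""Quality control and transformation of metabolite and taxa tables.

Metabolites: drop under-measured compounds, impute censored values with the
per-metabolite minimum, log10-transform, z-score. Taxa: drop rare taxa,
centered log-ratio (CLR) transform with zero replacement, and per-sample
alpha diversity (Chao1, Shannon, Simpson) on the count table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import shannon as _skbio_shannon
from skbio.diversity.alpha import simpson as _skbio_simpson

__all__ = [
    "PreprocessConfig",
    "PreprocessedTables",
    "filter_metabolites",
    "impute_and_standardize",
    "residualize_storage_time",
    "filter_taxa",
    "clr_transform",
    "alpha_diversity",
    "preprocess_study",
]


@dataclass
class PreprocessConfig:
    """Thresholds and switches for the QC/transform stage.

    Defaults follow the study conventions: metabolites need at least 50
    measurements; taxa need a strict >0.1% mean relative abundance and
    presence in strictly more than 10 samples; CLR zeros are replaced with
    1e-10; Shannon in bits and bias-corrected Chao1 (the QIIME 2 defaults);
    storage-time residualization is off because aging year is itself a
    predictor downstream.
    """

    metabolite_min_measurements: int = 50
    taxa_min_mean_abundance: float = 0.001
    taxa_min_measurements: int = 10
    clr_zero_replacement: float = 1e-10
    residualize_on_storage_time: bool = False
    shannon_base: float = 2.0
    chao1_bias_corrected: bool = True

    def __post_init__(self) -> None:
        if self.metabolite_min_measurements < 0 or self.taxa_min_measurements < 0:
            raise ValueError("thresholds must be nonnegative")
        if not 0 <= self.taxa_min_mean_abundance < 1:
            raise ValueError("taxa_min_mean_abundance must lie in [0, 1)")
        if self.clr_zero_replacement <= 0:
            raise ValueError("clr_zero_replacement must be positive")


def filter_metabolites(
    metabolites: pd.DataFrame, min_measurements: int = 50
) -> tuple[pd.DataFrame, list[str]]:
    """Keep metabolites with at least ``min_measurements`` non-missing
    values. Returns (filtered table, dropped metabolite IDs); column order
    is preserved."""
    n_obs = metabolites.notna().sum(axis=0)
    keep = n_obs >= min_measurements
    dropped = [c for c in metabolites.columns if not keep[c]]
    kept = metabolites.loc[:, keep]
    if kept.shape[1] == 0:
        raise ValueError(
            f"no metabolites survive the >= {min_measurements} measurements filter"
        )
    return kept, dropped


def impute_and_standardize(metabolites: pd.DataFrame) -> pd.DataFrame:
    """Minimum-impute, log10-transform and z-score each metabolite.

    Missing values become the per-metabolite minimum of the observed values
    (censored-at-detection-limit reading of missingness), then v -> log10(v),
    then per-column (v - mean) / sd with the sample (n-1) standard deviation.
    """
    out = metabolites.copy().astype(float)
    for col in out.columns:
        v = out[col]
        obs = v.dropna()
        if len(obs) == 0:
            raise ValueError(f"metabolite {col!r} has no observed values")
        if (obs <= 0).any():
            raise ValueError(f"metabolite {col!r} has nonpositive values; log10 undefined")
        out[col] = v.fillna(obs.min())
    logged = np.log10(out)
    sd = logged.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant metabolites cannot be standardized: {bad}")
    return (logged - logged.mean(axis=0)) / sd


def residualize_storage_time(
    metabolites: pd.DataFrame, storage_time: pd.Series
) -> tuple[pd.DataFrame, list[str]]:
    """Replace each (standardized) metabolite by the re-standardized
    residual of an OLS fit on storage time.

    A metabolite exactly linear in storage time has all-zero residuals; it
    is returned as zeros and listed in the second return value instead of
    raising, so callers can drop or flag it.
    """
    if storage_time.isna().any():
        raise ValueError("storage time is missing for some samples")
    t = storage_time.loc[metabolites.index].to_numpy(float)
    X = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(X, metabolites.to_numpy(float), rcond=None)
    resid = metabolites.to_numpy(float) - X @ coef
    sd = resid.std(axis=0, ddof=1)
    # metabolites arrive standardized (sd 1), so sd below 1e-8 means the
    # regression absorbed everything up to round-off
    is_const = sd < 1e-8
    constant = [c for c, flag in zip(metabolites.columns, is_const) if flag]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (resid - resid.mean(axis=0)) / sd
    z[:, is_const] = 0.0
    return pd.DataFrame(z, index=metabolites.index, columns=metabolites.columns), constant


def filter_taxa(
    relabund: pd.DataFrame,
    min_mean_abundance: float = 0.001,
    min_measurements: int = 10,
) -> tuple[pd.DataFrame, list[str]]:
    """Keep taxa with mean relative abundance strictly above
    ``min_mean_abundance`` AND nonzero abundance in strictly more than
    ``min_measurements`` samples. Rows are not renormalized: the CLR
    transform downstream is invariant to row rescaling."""
    if (relabund < 0).any().any():
        raise ValueError("relative abundances must be nonnegative")
    mean_ab = relabund.mean(axis=0)
    n_present = (relabund > 0).sum(axis=0)
    keep = (mean_ab > min_mean_abundance) & (n_present > min_measurements)
    dropped = [c for c in relabund.columns if not keep[c]]
    return relabund.loc[:, keep], dropped


def clr_transform(relabund: pd.DataFrame, zero_replacement: float = 1e-10) -> pd.DataFrame:
    """Centered log-ratio transform per sample over the retained taxa.

    Zeros (and any value below ``zero_replacement``) are floored at
    ``zero_replacement`` before taking logs; each output row sums to 0.
    """
    x = relabund.to_numpy(float)
    if (x < 0).any():
        raise ValueError("relative abundances must be nonnegative")
    x = np.maximum(x, zero_replacement)
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=relabund.index, columns=relabund.columns)


def alpha_diversity(
    taxa_counts: pd.DataFrame,
    shannon_base: float = 2.0,
    chao1_bias_corrected: bool = True,
) -> pd.DataFrame:
    """Per-sample Chao1 richness, Shannon entropy and Simpson (1 - sum p²).

    Chao1 uses the bias-corrected small-sample form
    S_obs + F1(F1-1)/(2(F2+1)) by default; Shannon defaults to bits.
    """
    counts = taxa_counts.to_numpy()
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if (counts.sum(axis=1) == 0).any():
        bad = list(taxa_counts.index[counts.sum(axis=1) == 0])
        raise ValueError(f"samples with all-zero counts: {bad}")
    rows = {
        "chao1": [_skbio_chao1(r, bias_corrected=chao1_bias_corrected) for r in counts],
        "shannon": [_skbio_shannon(r, base=shannon_base) for r in counts],
        "simpson": [_skbio_simpson(r) for r in counts],
    }
    return pd.DataFrame(rows, index=taxa_counts.index, dtype=float)


@dataclass
class PreprocessedTables:
    """Everything downstream modeling consumes, sample-aligned.

    metabolites are standardized (mean 0, sd 1); clr_* are CLR-transformed
    filtered taxa at the two annotation levels; diversity_* are alpha
    diversity indices computed from the counts at the matching level.
    """

    metabolites: pd.DataFrame
    clr_species: pd.DataFrame
    clr_genus: pd.DataFrame
    diversity_species: pd.DataFrame
    diversity_genus: pd.DataFrame
    physio: pd.DataFrame
    aging_year: pd.Series
    dropped_metabolites: list[str]
    dropped_species: list[str]
    dropped_genera: list[str]


def preprocess_study(tables, config: PreprocessConfig | None = None) -> PreprocessedTables:
    """Run the full QC/transform stage on a :class:`~brewlink.simulate.StudyTables`.

    Order matters and mirrors standard practice: metabolites are filtered,
    min-imputed, log10-z-scored (optionally residualized on storage time);
    taxa are filtered before the CLR transform so the log-ratio mean runs
    over retained taxa only; alpha diversity is computed on the *unfiltered*
    counts (richness estimators need the rare taxa).
    """
    cfg = config or PreprocessConfig()

    mets, dropped_m = filter_metabolites(tables.metabolites, cfg.metabolite_min_measurements)
    mets = impute_and_standardize(mets)
    if cfg.residualize_on_storage_time:
        mets, constant = residualize_storage_time(mets, tables.aging_year)
        if constant:
            mets = mets.drop(columns=constant)
            dropped_m = dropped_m + constant

    rel_sp = tables.taxa_relabund
    rel_ge = tables.genus_relabund()
    sp_kept, dropped_sp = filter_taxa(
        rel_sp, cfg.taxa_min_mean_abundance, cfg.taxa_min_measurements
    )
    ge_kept, dropped_ge = filter_taxa(
        rel_ge, cfg.taxa_min_mean_abundance, cfg.taxa_min_measurements
    )
    clr_sp = clr_transform(sp_kept, cfg.clr_zero_replacement)
    clr_ge = clr_transform(ge_kept, cfg.clr_zero_replacement)

    div_sp = alpha_diversity(tables.taxa_counts, cfg.shannon_base, cfg.chao1_bias_corrected)
    div_ge = alpha_diversity(tables.genus_counts(), cfg.shannon_base, cfg.chao1_bias_corrected)

    return PreprocessedTables(
        metabolites=mets,
        clr_species=clr_sp,
        clr_genus=clr_ge,
        diversity_species=div_sp,
        diversity_genus=div_ge,
        physio=tables.physio.copy(),
        aging_year=tables.aging_year.astype(float),
        dropped_metabolites=dropped_m,
        dropped_species=dropped_sp,
        dropped_genera=dropped_ge,
    )
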