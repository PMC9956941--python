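"""Assembly of the six named feature groups.

Groups are ablations of the full predictor set:

====  =======================================================
FM    everything below (aging year included once)
PI    the five physiochemical indexes + aging year
AFS   aging year + species-level microbiome (CLR + diversity)
AMS   species-level microbiome only
AFG   aging year + genus-level microbiome (CLR + diversity)
AMG   genus-level microbiome only
====  =======================================================

"Microbiome" always means the CLR-transformed filtered abundances plus the
three alpha-diversity indices computed at the matching annotation level.
Diversity columns carry a level suffix (``chao1_species`` vs ``chao1_genus``)
so the full model keeps both without collision.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .preprocess import PreprocessedTables

__all__ = ["FEATURE_GROUPS", "FeatureMatrix", "assemble_features", "feature_provenance"]

FEATURE_GROUPS = ("FM", "PI", "AFS", "AMS", "AFG", "AMG")

#: provenance tags, attached per column
_BLOCKS = ("physio", "year", "clr-species", "clr-genus", "diversity-species", "diversity-genus")

_GROUP_BLOCKS: dict[str, tuple[str, ...]] = {
    "PI": ("physio", "year"),
    "AMS": ("clr-species", "diversity-species"),
    "AFS": ("year", "clr-species", "diversity-species"),
    "AMG": ("clr-genus", "diversity-genus"),
    "AFG": ("year", "clr-genus", "diversity-genus"),
    "FM": _BLOCKS,
}


class FeatureMatrix(pd.DataFrame):
    """A samples × features table with a per-column provenance tag.

    Plain DataFrame plus a ``provenance`` dict (column -> block name) and
    the group ``name``; survives slicing as a normal DataFrame.
    """

    _metadata = ["provenance", "name"]

    @property
    def _constructor(self):
        return FeatureMatrix


def _block_frames(prep: PreprocessedTables) -> dict[str, pd.DataFrame]:
    div_sp = prep.diversity_species.add_suffix("_species")
    div_ge = prep.diversity_genus.add_suffix("_genus")
    return {
        "physio": prep.physio,
        "year": prep.aging_year.to_frame("aging_year"),
        "clr-species": prep.clr_species,
        "clr-genus": prep.clr_genus,
        "diversity-species": div_sp,
        "diversity-genus": div_ge,
    }


def assemble_features(name: str, prep: PreprocessedTables) -> FeatureMatrix:
    """Build the feature matrix for one named group.

    Columns come in fixed block order, alphabetical within each block;
    constant columns are dropped with a warning (they carry no signal and
    break standardization-based attribution).
    """
    if name not in _GROUP_BLOCKS:
        raise ValueError(f"unknown feature group {name!r}; expected one of {FEATURE_GROUPS}")
    blocks = _block_frames(prep)
    for b in _GROUP_BLOCKS[name]:
        if "species" in b and blocks[b].shape[1] == 0:
            raise ValueError(f"feature group {name} needs species-level taxa, none available")
        if "genus" in b and blocks[b].shape[1] == 0:
            raise ValueError(f"feature group {name} needs genus-level taxa, none available")

    parts: list[pd.DataFrame] = []
    provenance: dict[str, str] = {}
    for b in _GROUP_BLOCKS[name]:
        frame = blocks[b].loc[:, sorted(blocks[b].columns)]
        parts.append(frame)
        provenance.update({c: b for c in frame.columns})
    X = pd.concat(parts, axis=1)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"feature columns with missing values: {bad}")
    const = X.columns[X.nunique() <= 1]
    if len(const):
        warnings.warn(f"dropping constant feature columns: {list(const)}", stacklevel=2)
        X = X.drop(columns=list(const))
        for c in const:
            provenance.pop(c, None)
    out = FeatureMatrix(X)
    out.provenance = provenance
    out.name = name
    return out


def feature_provenance(X: FeatureMatrix) -> pd.Series:
    """Provenance tag per column, as a Series aligned to the columns."""
    return pd.Series({c: X.provenance[c] for c in X.columns}, name="provenance")
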