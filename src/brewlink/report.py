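"""Descriptive association layer: Spearman correlation screens, the
two-way cluster map of well-predicted metabolites, and one-way ANOVA of an
index across sample clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "spearman_association",
    "ClusterMapResult",
    "cluster_metabolite_map",
    "anova_by_cluster",
    "linkage_to_newick",
]


def spearman_association(
    table_a: pd.DataFrame, table_b: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and two-sided p between the columns of two
    sample-aligned tables (or within one table).

    Missing values are handled pairwise-complete; pairs with fewer than 3
    complete observations are reported as NaN. Ties get average ranks and p
    comes from the t approximation.
    """
    sym = table_b is None
    if table_b is None:
        table_b = table_a
    if not table_a.index.equals(table_b.index):
        raise ValueError("tables are not sample-aligned")
    rho = pd.DataFrame(np.nan, index=table_a.columns, columns=table_b.columns)
    pval = rho.copy()
    for ca in table_a.columns:
        a = table_a[ca]
        for cb in table_b.columns:
            if sym and not pd.isna(rho.at[cb, ca]):
                rho.at[ca, cb] = rho.at[cb, ca]
                pval.at[ca, cb] = pval.at[cb, ca]
                continue
            b = table_b[cb]
            ok = a.notna() & b.notna()
            if ok.sum() < 3:
                continue
            r, p = stats.spearmanr(a[ok], b[ok])
            rho.at[ca, cb] = r
            pval.at[ca, cb] = p
    return rho, pval


@dataclass
class ClusterMapResult:
    """Two-way hierarchical clustering of the well-predicted metabolites."""

    metabolite_labels: pd.Series   # metabolite -> MC cluster id (1-based)
    sample_labels: pd.Series       # sample -> SC cluster id (1-based)
    metabolite_linkage: np.ndarray
    sample_linkage: np.ndarray
    retained: list[str]
    ev_threshold: float

    def summary(self) -> str:
        mc = self.metabolite_labels.value_counts().sort_index()
        sc = self.sample_labels.value_counts().sort_index()
        lines = [f"Cluster map of {len(self.retained)} metabolites (EV > {self.ev_threshold})"]
        lines += [f"  MC-{k}: {v} metabolites" for k, v in mc.items()]
        lines += [f"  SC-{k}: {v} samples" for k, v in sc.items()]
        return "\n".join(lines)


def _relabel_by_first_occurrence(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster ids 1..k in order of first appearance, making labels
    independent of scipy's internal numbering."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def cluster_metabolite_map(
    metabolites: pd.DataFrame,
    ev: pd.Series,
    threshold: float = 0.3,
    n_metabolite_clusters: int = 3,
    n_sample_clusters: int = 3,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterMapResult:
    """Cluster the standardized metabolite matrix restricted to metabolites
    with explained variance above ``threshold``, on both axes.

    Metabolite columns are processed in sorted-name order so cluster labels
    do not depend on input column order.
    """
    retained = sorted(c for c in metabolites.columns if c in ev.index and ev[c] > threshold)
    if len(retained) == 0:
        raise ValueError(f"no metabolites with EV > {threshold}")
    if len(retained) < 2:
        raise ValueError("need at least 2 well-predicted metabolites to cluster")
    M = metabolites[retained]
    met_link = hierarchy.linkage(M.T.to_numpy(), method=method, metric=metric)
    smp_link = hierarchy.linkage(M.to_numpy(), method=method, metric=metric)
    met_lab = hierarchy.fcluster(met_link, t=n_metabolite_clusters, criterion="maxclust")
    smp_lab = hierarchy.fcluster(smp_link, t=n_sample_clusters, criterion="maxclust")
    return ClusterMapResult(
        metabolite_labels=pd.Series(
            _relabel_by_first_occurrence(met_lab), index=retained, name="MC"
        ),
        sample_labels=pd.Series(
            _relabel_by_first_occurrence(smp_lab), index=M.index, name="SC"
        ),
        metabolite_linkage=met_link,
        sample_linkage=smp_link,
        retained=retained,
        ev_threshold=threshold,
    )


def anova_by_cluster(values: pd.Series, labels: pd.Series) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of an index across sample clusters.

    Returns (F, p); zero within-group variance with separated means gives
    F = +inf, p = 0.
    """
    if not values.index.equals(labels.index):
        values = values.loc[labels.index]
    groups = [values[labels == g].to_numpy(float) for g in sorted(labels.unique())]
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters")
    for g, arr in zip(sorted(labels.unique()), groups):
        if len(arr) < 2:
            raise ValueError(f"cluster {g} has fewer than 2 samples")
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")  # scipy warns on zero within-group variance
        f, p = stats.f_oneway(*groups)
    if np.isnan(f):  # all groups constant and equal
        raise ValueError("ANOVA undefined: zero between- and within-group variance")
    if np.isinf(f):
        return float("inf"), 0.0
    return float(f), float(p)


def linkage_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch
    lengths derived from merge heights."""
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.get_left(), tree.dist)},{rec(tree.get_right(), tree.dist)});"
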