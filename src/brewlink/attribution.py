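"""Directional mean-absolute-SHAP feature attribution.

For every fitted tree-ensemble fold model, SHAP values are computed on the
held-out fold (so attribution reflects generalizable structure, not
training fit), pooled across the folds of a run, summarized per feature as
the mean absolute SHAP value, and averaged over repeated runs. Each
feature's summary is then signed by the Spearman correlation between the
raw feature column and the metabolite over all samples:

    directional = mean|SHAP| × sign(spearman rho)

Because metabolites and CLR features are standardized upstream, these
values are comparable across metabolites. Features with an exactly zero or
undefined correlation (constant columns) get sign 0 and a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .shapley import shapley_values

__all__ = ["AttributionResult", "directional_attribution", "attribution_matrix"]


@dataclass
class AttributionResult:
    """Per-feature attribution for one (metabolite, feature group) model."""

    metabolite: str
    feature_group: str
    table: pd.DataFrame  # index: feature; mean_abs_shap, spearman_sign, directional_mean_abs_shap
    base_value: float

    def top_features(self, n: int = 10) -> pd.DataFrame:
        return self.table.sort_values("mean_abs_shap", ascending=False).head(n)

    def summary(self) -> str:
        lines = [
            f"Attribution of {self.metabolite} [{self.feature_group or '-'}]",
            "=" * 56,
            f"{'feature':<28}{'mean|SHAP|':>12}{'directional':>14}",
            "-" * 56,
        ]
        for feat, row in self.top_features(8).iterrows():
            lines.append(
                f"{feat:<28}{row.mean_abs_shap:>12.4f}{row.directional_mean_abs_shap:>+14.4f}"
            )
        lines.append("=" * 56)
        return "\n".join(lines)

    def plot_heatmap(self, ax=None):
        """Bar view of directional mean-|SHAP| for the strongest features."""
        import matplotlib.pyplot as plt

        top = self.top_features(15).iloc[::-1]
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 0.3 * len(top) + 1))
        colors = ["#b2182b" if v > 0 else "#2166ac" for v in top.directional_mean_abs_shap]
        ax.barh(top.index, top.directional_mean_abs_shap, color=colors)
        ax.axvline(0, c="k", lw=0.8)
        ax.set_xlabel("directional mean |SHAP| (z units)")
        ax.set_title(f"{self.metabolite} [{self.feature_group}]")
        return ax


def _spearman_signs(X: pd.DataFrame, y: pd.Series) -> pd.Series:
    signs = {}
    yv = y.to_numpy(float)
    for col in X.columns:
        xv = X[col].to_numpy(float)
        if np.unique(xv).size <= 1:
            warnings.warn(f"feature {col!r} is constant; attribution sign set to 0", stacklevel=3)
            signs[col] = 0
            continue
        rho = stats.spearmanr(xv, yv).statistic
        signs[col] = 0 if (np.isnan(rho) or rho == 0) else int(np.sign(rho))
    return pd.Series(signs, name="spearman_sign")


def directional_attribution(results, on: str = "test") -> AttributionResult:
    """Aggregate SHAP attribution of a fitted :class:`PredictionResults`.

    ``on='test'`` (default) attributes each fold model on its held-out
    samples; ``on='train'`` is a diagnostic switch attributing on the
    training folds instead. Requires a tree-ensemble learner.
    """
    model = results.model
    if not model.learner.is_tree_ensemble:
        raise TypeError(
            "Shapley attribution needs a tree-ensemble learner; "
            f"{model.learner.kind!r} is not supported"
        )
    if on not in ("test", "train"):
        raise ValueError("on must be 'test' or 'train'")
    X = model.X
    Xv = X.to_numpy(float)
    n = len(model.y)
    per_run = []
    bases = []
    for cv in results.runs:
        abs_sum = np.zeros(X.shape[1])
        n_pooled = 0
        for fm in cv.fold_models:
            idx = (
                fm.test_index
                if on == "test"
                else np.setdiff1d(np.arange(n), fm.test_index)
            )
            phi, base = shapley_values(fm.estimator, Xv[idx])
            abs_sum += np.abs(phi).sum(axis=0)
            n_pooled += len(idx)
            bases.append(base)
        per_run.append(abs_sum / n_pooled)
    mean_abs = pd.Series(np.mean(per_run, axis=0), index=X.columns, name="mean_abs_shap")
    signs = _spearman_signs(X, model.y)
    table = pd.DataFrame(
        {
            "mean_abs_shap": mean_abs,
            "spearman_sign": signs,
            "directional_mean_abs_shap": mean_abs * signs,
        }
    )
    return AttributionResult(
        metabolite=results.metabolite,
        feature_group=model.feature_group,
        table=table,
        base_value=float(np.mean(bases)),
    )


def attribution_matrix(attributions: list[AttributionResult]) -> pd.DataFrame:
    """Wide metabolite × feature matrix of directional mean-|SHAP| values,
    the data behind an attribution heat map."""
    rows = {
        a.metabolite: a.table["directional_mean_abs_shap"] for a in attributions
    }
    return pd.DataFrame(rows).T.fillna(0.0)
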