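"""Bootstrap significance of the cross-validated explained variance.

Each bootstrap iteration draws a fresh k-fold partition, resamples every
*training* fold with replacement to its original size (held-out folds are
never resampled), trains, predicts the untouched held-out fold, and pools
the out-of-fold predictions into one explained-variance value. The B
iteration values give a 95% percentile confidence interval and a one-sided
empirical p-value against the "no variance explained" null:

    p = (1 + #{EV_b <= 0}) / (B + 1)

so p is bounded below by 1/(B+1) and a metabolite is called significantly
explained when p < alpha. Hyperparameters are the learner's fixed (or
previously selected) configuration; no search runs inside the bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .learners import LearnerSpec, build_estimator
from .model import _child_seed, explained_variance

__all__ = ["BootstrapResult", "bootstrap_significance", "benjamini_hochberg"]


@dataclass
class BootstrapResult:
    """Bootstrap distribution and derived inference for one metabolite."""

    metabolite: str
    feature_group: str
    learner: str
    point_ev: float
    distribution: np.ndarray
    ci_low: float
    ci_high: float
    p_value: float
    alpha: float
    degenerate: bool = False  # single-iteration CI

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def summary(self) -> str:
        flag = "significant" if self.significant else "not significant"
        return (
            f"{self.metabolite} [{self.feature_group or '-'}] {self.learner}: "
            f"EV={self.point_ev:+.3f}, 95% CI [{self.ci_low:+.3f}, {self.ci_high:+.3f}], "
            f"p={self.p_value:.4g} ({flag} at alpha={self.alpha})"
        )


def bootstrap_significance(
    X: pd.DataFrame,
    y: pd.Series,
    learner: LearnerSpec | str,
    iterations: int = 100,
    k: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
    metabolite: str | None = None,
    feature_group: str = "",
) -> BootstrapResult:
    """Bootstrap CI and p-value for the out-of-fold explained variance."""
    spec = LearnerSpec.default(learner) if isinstance(learner, str) else learner
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if iterations < 20:
        warnings.warn(
            f"{iterations} bootstrap iterations give an unstable 95% CI", stacklevel=2
        )
    Xv = X.to_numpy(float)
    yv = y.to_numpy(float)
    n = len(yv)

    ss = np.random.SeedSequence(seed)
    point_seed, boot_seed = (_child_seed(s) for s in ss.spawn(2))

    # point estimate: one plain CV with the learner's fixed configuration
    from .model import cross_validated_predict

    spec_fixed = LearnerSpec(
        kind=spec.kind, params=dict(spec.params), search_iterations=0
    )
    point = cross_validated_predict(
        X, y, spec_fixed, k=k, seed=point_seed, metabolite=metabolite,
        feature_group=feature_group,
    ).explained_variance

    evs = np.empty(iterations)
    for b in range(iterations):
        b_ss = np.random.SeedSequence(boot_seed, spawn_key=(b,))
        fold_seed = _child_seed(b_ss)
        rng = np.random.default_rng(b_ss.spawn(1)[0])
        kf = KFold(n_splits=k, shuffle=True, random_state=fold_seed % (2**32 - 1))
        oof = np.full(n, np.nan)
        for tr, te in kf.split(Xv):
            boot_tr = rng.choice(tr, size=len(tr), replace=True)
            est = build_estimator(spec_fixed, Xv.shape[1], random_state=fold_seed % (2**31))
            est.fit(Xv[boot_tr], yv[boot_tr])
            oof[te] = est.predict(Xv[te])
        evs[b] = explained_variance(yv, oof)

    ci_low, ci_high = np.percentile(evs, [2.5, 97.5])
    p = (1.0 + np.sum(evs <= 0.0)) / (iterations + 1.0)
    return BootstrapResult(
        metabolite=str(metabolite if metabolite is not None else (y.name or "y")),
        feature_group=feature_group,
        learner=spec.kind,
        point_ev=point,
        distribution=evs,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(p),
        alpha=alpha,
        degenerate=iterations == 1,
    )


def benjamini_hochberg(p_values: pd.Series) -> pd.Series:
    """BH-adjusted q-values; off by default in the pipeline, provided for
    users who model many metabolites and want FDR control."""
    p = p_values.to_numpy(float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return pd.Series(out, index=p_values.index, name="q_value")
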