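"""Per-metabolite cross-validated prediction.

The central objects follow the model/results convention of mainstream
statistics packages: :class:`MetabolitePredictor` holds data (a feature
matrix and one standardized metabolite) plus a learner spec; ``fit()``
returns :class:`PredictionResults` carrying out-of-fold predictions,
explained variance and R² per repeated run, a ``summary()`` table, and the
``bootstrap()`` / ``attribution()`` follow-ups.

Scoring is on pooled out-of-fold predictions: every sample is predicted
exactly once per run by a model that never saw it, and explained variance /
R² compare that prediction vector against the observed values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .learners import LearnerSpec, build_estimator, sample_search_params

__all__ = [
    "explained_variance",
    "coefficient_of_determination",
    "CVResult",
    "cross_validated_predict",
    "MetabolitePredictor",
    "PredictionResults",
    "compare_learners",
    "LearnerComparison",
]


def explained_variance(y: np.ndarray, yhat: np.ndarray) -> float:
    """EV = 1 - Var(y - yhat) / Var(y).

    Unlike R², insensitive to a constant prediction offset. Variances use
    the sample (n-1) denominator; the ratio is denominator-invariant.
    """
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    vy = y.var(ddof=1)
    if vy == 0:
        raise ValueError("explained variance undefined for constant y")
    return float(1.0 - (y - yhat).var(ddof=1) / vy)


def coefficient_of_determination(y: np.ndarray, yhat: np.ndarray) -> float:
    """R² = 1 - SS_res / SS_tot; can be negative for out-of-fold predictions."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R² undefined for constant y")
    return float(1.0 - ((y - yhat) ** 2).sum() / ss_tot)


@dataclass
class FoldModel:
    """A fitted per-fold estimator and its held-out sample positions."""

    estimator: object
    test_index: np.ndarray
    chosen_params: dict


@dataclass
class CVResult:
    """One repeated run of k-fold cross-validated prediction."""

    metabolite: str
    feature_group: str
    learner: str
    run: int
    oof: pd.Series
    explained_variance: float
    r_squared: float
    fold_models: list[FoldModel] = field(repr=False, default_factory=list)


def _stable_hash(s: str) -> int:
    return zlib.crc32(s.encode()) & 0x7FFFFFFF


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _search_best_params(
    X: np.ndarray,
    y: np.ndarray,
    spec: LearnerSpec,
    rng: np.random.Generator,
    inner_seed: int,
) -> dict:
    """Random hyperparameter search: the configured number of random draws,
    each scored by 3-fold inner cross-validated explained variance on the
    training fold; ties broken by draw order."""
    if spec.search_iterations <= 0:
        return {}
    inner = KFold(n_splits=3, shuffle=True, random_state=inner_seed % (2**32 - 1))
    splits = list(inner.split(X))
    best_score, best_params = -np.inf, {}
    for _ in range(spec.search_iterations):
        params = sample_search_params(spec, rng)
        scores = []
        for tr, te in splits:
            est = build_estimator(spec, X.shape[1], random_state=inner_seed % (2**31), overrides=params)
            est.fit(X[tr], y[tr])
            pred = est.predict(X[te])
            # inner score: negative MSE (EV can be undefined on tiny folds)
            scores.append(-float(((y[te] - pred) ** 2).mean()))
        score = float(np.mean(scores))
        if score > best_score:
            best_score, best_params = score, params
    return best_params


def cross_validated_predict(
    X: pd.DataFrame,
    y: pd.Series,
    learner: LearnerSpec | str,
    k: int = 5,
    seed: int = 0,
    metabolite: str | None = None,
    feature_group: str = "",
    run: int = 0,
) -> CVResult:
    """k-fold out-of-fold prediction of one metabolite.

    The fold partition, the hyperparameter search draws and the estimator
    seeds all derive from ``seed``, so the result is deterministic. Within
    each training fold the search (if enabled) picks a configuration by
    inner 3-fold CV; the estimator is then refit on the whole training fold
    and predicts the held-out fold.
    """
    spec = LearnerSpec.default(learner) if isinstance(learner, str) else learner
    if y.isna().any():
        raise ValueError("y contains missing values; preprocess first")
    if y.nunique() <= 1:
        raise ValueError("y is constant; nothing to predict")
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} samples")
    if not X.index.equals(y.index):
        raise ValueError("feature matrix and y are not sample-aligned")

    ss = np.random.SeedSequence(seed)
    fold_ss, search_ss, est_ss = ss.spawn(3)
    kf = KFold(n_splits=k, shuffle=True, random_state=_child_seed(fold_ss) % (2**32 - 1))

    Xv = X.to_numpy(float)
    yv = y.to_numpy(float)
    oof = np.full(n, np.nan)
    fold_models: list[FoldModel] = []
    for fold_idx, (tr, te) in enumerate(kf.split(Xv)):
        rng = np.random.default_rng(
            np.random.SeedSequence(_child_seed(search_ss), spawn_key=(fold_idx,))
        )
        inner_seed = _child_seed(np.random.SeedSequence(_child_seed(est_ss), spawn_key=(fold_idx,)))
        best = _search_best_params(Xv[tr], yv[tr], spec, rng, inner_seed)
        est = build_estimator(spec, Xv.shape[1], random_state=inner_seed % (2**31), overrides=best)
        est.fit(Xv[tr], yv[tr])
        oof[te] = est.predict(Xv[te])
        fold_models.append(FoldModel(est, te, best))

    assert not np.isnan(oof).any()
    name = metabolite if metabolite is not None else (y.name or "y")
    return CVResult(
        metabolite=str(name),
        feature_group=feature_group,
        learner=spec.kind,
        run=run,
        oof=pd.Series(oof, index=y.index, name=name),
        explained_variance=explained_variance(yv, oof),
        r_squared=coefficient_of_determination(yv, oof),
        fold_models=fold_models,
    )


class MetabolitePredictor:
    """Model object: one metabolite, one feature group, one learner.

    Parameters
    ----------
    X : feature matrix (samples × features), no missing values.
    y : the standardized metabolite, sample-aligned with X.
    learner : a :class:`LearnerSpec` or a learner kind string.
    k : number of cross-validation folds.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y: pd.Series,
        learner: LearnerSpec | str = "random_forest",
        k: int = 5,
        feature_group: str | None = None,
    ) -> None:
        self.X = X
        self.y = y
        self.learner = LearnerSpec.default(learner) if isinstance(learner, str) else learner
        self.k = k
        self.feature_group = feature_group or getattr(X, "name", "") or ""
        if len(y) < 2 * k:
            raise ValueError(f"need at least {2 * k} samples for {k}-fold CV")

    @classmethod
    def from_tables(
        cls,
        tables,
        metabolite: str,
        feature_group: str = "FM",
        learner: LearnerSpec | str = "random_forest",
        k: int = 5,
        preprocess_config=None,
    ) -> "MetabolitePredictor":
        """Build from raw :class:`~brewlink.simulate.StudyTables`: runs the
        preprocessing stage and assembles the requested feature group."""
        from .features import assemble_features
        from .preprocess import preprocess_study

        prep = preprocess_study(tables, preprocess_config)
        if metabolite not in prep.metabolites.columns:
            raise KeyError(f"metabolite {metabolite!r} absent after preprocessing")
        X = assemble_features(feature_group, prep)
        return cls(X, prep.metabolites[metabolite], learner, k, feature_group)

    def fit(self, runs: int = 1, seed: int = 0) -> "PredictionResults":
        """Repeat seeded cross-validated prediction ``runs`` times.

        Each (metabolite, run) pair gets its own fold partition derived
        from the global seed, the metabolite name and the run index.
        """
        results = []
        met = str(self.y.name or "y")
        for r in range(runs):
            run_seed = int(
                np.random.SeedSequence(seed, spawn_key=(_stable_hash(met), r)).generate_state(1)[0]
            )
            results.append(
                cross_validated_predict(
                    self.X,
                    self.y,
                    self.learner,
                    k=self.k,
                    seed=run_seed,
                    metabolite=met,
                    feature_group=self.feature_group,
                    run=r,
                )
            )
        return PredictionResults(self, results, seed)


class PredictionResults:
    """Fitted results: per-run out-of-fold predictions and scores.

    Attributes
    ----------
    explained_variance_ : per-run EV (np.ndarray, length runs)
    r_squared_ : per-run R²
    oof_predictions : DataFrame (samples × runs)
    """

    def __init__(self, model: MetabolitePredictor, runs: list[CVResult], seed: int) -> None:
        self.model = model
        self.runs = runs
        self.seed = seed
        self.explained_variance_ = np.array([r.explained_variance for r in runs])
        self.r_squared_ = np.array([r.r_squared for r in runs])
        self.oof_predictions = pd.concat(
            {r.run: r.oof for r in runs}, axis=1
        )

    @property
    def metabolite(self) -> str:
        return self.runs[0].metabolite

    def summary(self) -> str:
        ev, r2 = self.explained_variance_, self.r_squared_
        lines = [
            "Metabolite prediction results",
            "=" * 46,
            f"metabolite:        {self.metabolite}",
            f"feature group:     {self.model.feature_group or '-'}",
            f"learner:           {self.model.learner.kind}",
            f"folds / runs:      {self.model.k} / {len(self.runs)}",
            f"n samples/features:{len(self.model.y)} / {self.model.X.shape[1]}",
            "-" * 46,
            f"explained variance {ev.mean():+.4f} (sd {ev.std(ddof=0):.4f})",
            f"R²                 {r2.mean():+.4f} (sd {r2.std(ddof=0):.4f})",
            "=" * 46,
        ]
        return "\n".join(lines)

    def bootstrap(self, iterations: int = 100, alpha: float = 0.05, seed: int | None = None):
        """Bootstrap CI and p-value for the explained variance; see
        :func:`brewlink.significance.bootstrap_significance`."""
        from .significance import bootstrap_significance

        return bootstrap_significance(
            self.model.X,
            self.model.y,
            self.model.learner,
            iterations=iterations,
            k=self.model.k,
            alpha=alpha,
            seed=self.seed if seed is None else seed,
            metabolite=self.metabolite,
            feature_group=self.model.feature_group,
        )

    def attribution(self, on: str = "test"):
        """Directional mean-|SHAP| attribution of the fitted tree-ensemble
        fold models; see :func:`brewlink.attribution.directional_attribution`."""
        from .attribution import directional_attribution

        return directional_attribution(self, on=on)

    def plot_predictions(self, run: int = 0, ax=None):
        """Measured vs out-of-fold predicted scatter for one run."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(self.model.y, self.oof_predictions[run], s=18, alpha=0.8)
        lims = [
            min(self.model.y.min(), self.oof_predictions[run].min()),
            max(self.model.y.max(), self.oof_predictions[run].max()),
        ]
        ax.plot(lims, lims, ls="--", c="grey", lw=1)
        ax.set_xlabel(f"measured {self.metabolite} (z)")
        ax.set_ylabel("out-of-fold predicted (z)")
        ax.set_title(
            f"{self.metabolite} [{self.model.feature_group}] EV={self.runs[run].explained_variance:.2f}"
        )
        return ax


@dataclass
class LearnerComparison:
    """Outcome of the learner benchmark: per-run counts of well-predicted
    metabolites per learner, and per-metabolite score deltas."""

    counts_r2: pd.DataFrame       # learners × runs, count of metabolites with R² > threshold
    counts_ev: pd.DataFrame       # same on explained variance
    scores: pd.DataFrame          # long: metabolite, learner, run, ev, r2
    threshold: float

    def summary(self) -> str:
        lines = [
            f"Well-predicted metabolite counts (R² > {self.threshold})",
            "=" * 52,
        ]
        for learner in self.counts_r2.index:
            c = self.counts_r2.loc[learner]
            lines.append(f"{learner:<24} {c.mean():5.1f} ± {c.std(ddof=1 if len(c) > 1 else 0):.1f}")
        lines.append("=" * 52)
        return "\n".join(lines)

    def delta(self, learner_a: str, learner_b: str) -> pd.Series:
        """Per-metabolite mean-EV difference (a minus b) across runs."""
        m = self.scores.groupby(["learner", "metabolite"])["ev"].mean()
        return (m.loc[learner_a] - m.loc[learner_b]).rename(f"{learner_a}-{learner_b}")


def compare_learners(
    X: pd.DataFrame,
    metabolites: pd.DataFrame,
    learners: Sequence[LearnerSpec | str],
    runs: int = 10,
    k: int = 5,
    r2_threshold: float = 0.3,
    seed: int = 0,
    feature_group: str = "",
) -> LearnerComparison:
    """Benchmark learners on a common feature matrix over all metabolites.

    For every learner and run, counts the metabolites predicted with
    R² > threshold (and, separately, EV > threshold); fold partitions are
    shared across learners within a (metabolite, run) pair so the
    comparison is paired.
    """
    specs = [LearnerSpec.default(l) if isinstance(l, str) else l for l in learners]
    if len(specs) < 2:
        raise ValueError("need at least 2 learners to compare")
    rows = []
    for met in metabolites.columns:
        y = metabolites[met]
        for r in range(runs):
            run_seed = int(
                np.random.SeedSequence(seed, spawn_key=(_stable_hash(met), r)).generate_state(1)[0]
            )
            for spec in specs:
                res = cross_validated_predict(
                    X, y, spec, k=k, seed=run_seed, metabolite=met,
                    feature_group=feature_group, run=r,
                )
                rows.append(
                    {
                        "metabolite": met,
                        "learner": spec.kind,
                        "run": r,
                        "ev": res.explained_variance,
                        "r2": res.r_squared,
                    }
                )
    scores = pd.DataFrame(rows)
    counts_r2 = (
        scores.assign(hit=scores.r2 > r2_threshold)
        .pivot_table(index="learner", columns="run", values="hit", aggfunc="sum")
        .astype(int)
    )
    counts_ev = (
        scores.assign(hit=scores.ev > r2_threshold)
        .pivot_table(index="learner", columns="run", values="hit", aggfunc="sum")
        .astype(int)
    )
    return LearnerComparison(counts_r2, counts_ev, scores, r2_threshold)
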