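"""End-to-end orchestration: preprocess -> feature groups -> cross-validated
models -> bootstrap significance -> attribution -> descriptive reports,
with every output written as TSV/JSON under one output directory and a
manifest capturing the config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._io import FLOAT_FMT, read_study_tables, write_table
from .attribution import attribution_matrix
from .features import FEATURE_GROUPS, assemble_features
from .learners import LearnerSpec
from .model import MetabolitePredictor
from .preprocess import PreprocessConfig, preprocess_study
from .report import anova_by_cluster, cluster_metabolite_map, linkage_to_newick, spearman_association
from .simulate import StudyTables

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; serializable to/from YAML.

    Defaults are the study conventions: 5-fold CV, 10 repeated runs,
    100 bootstrap iterations, EV > 0.3 for the cluster map, random forest
    with fixed parameters as the main learner.
    """

    input_dir: str = ""
    output_dir: str = "brewlink_out"
    feature_groups: tuple[str, ...] = FEATURE_GROUPS
    learner: str = "random_forest"
    runs: int = 10
    k_folds: int = 5
    bootstrap_iterations: int = 100
    alpha: float = 0.05
    ev_threshold: float = 0.3
    cluster_feature_group: str = "PI"
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    metabolites: tuple[str, ...] | None = None  # subset; None = all surviving QC

    def __post_init__(self) -> None:
        unknown = set(self.feature_groups) - set(FEATURE_GROUPS)
        if unknown:
            raise ValueError(f"unknown feature groups: {sorted(unknown)}")
        if self.cluster_feature_group not in self.feature_groups:
            raise ValueError("cluster_feature_group must be one of feature_groups")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        prep = PreprocessConfig(**raw.pop("preprocess", {}))
        for key in ("feature_groups", "metabolites"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(preprocess=prep, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature_groups"] = list(self.feature_groups)
        if self.metabolites is not None:
            d["metabolites"] = list(self.metabolites)
        return d


def run_pipeline(config: PipelineConfig, tables: StudyTables | None = None) -> Path:
    """Run every stage and write the results bundle; returns the output dir.

    ``tables`` may be passed directly (e.g. fresh from the simulator);
    otherwise they are read from ``config.input_dir``.
    """
    if tables is None:
        if not config.input_dir:
            raise ValueError("either pass tables or set input_dir")
        tables = read_study_tables(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    prep = preprocess_study(tables, config.preprocess)
    write_table(prep.metabolites, out / "metabolites_standardized.tsv")
    write_table(prep.diversity_species, out / "alpha_diversity_species.tsv")
    write_table(prep.diversity_genus, out / "alpha_diversity_genus.tsv")
    stages.append("preprocess")

    met_names = list(prep.metabolites.columns)
    if config.metabolites is not None:
        missing = set(config.metabolites) - set(met_names)
        if missing:
            raise ValueError(f"requested metabolites absent after QC: {sorted(missing)}")
        met_names = [m for m in met_names if m in set(config.metabolites)]

    spec = LearnerSpec.default(config.learner)
    score_rows, sig_rows = [], []
    mean_ev: dict[str, pd.Series] = {}
    for group in config.feature_groups:
        X = assemble_features(group, prep)
        attributions = []
        group_ev = {}
        for met in met_names:
            predictor = MetabolitePredictor(
                X, prep.metabolites[met], spec, k=config.k_folds, feature_group=group
            )
            res = predictor.fit(runs=config.runs, seed=config.seed)
            for cv in res.runs:
                score_rows.append(
                    {
                        "metabolite": met,
                        "feature_group": group,
                        "learner": spec.kind,
                        "run": cv.run,
                        "explained_variance": cv.explained_variance,
                        "r_squared": cv.r_squared,
                    }
                )
            group_ev[met] = float(res.explained_variance_.mean())
            boot = res.bootstrap(
                iterations=config.bootstrap_iterations, alpha=config.alpha
            )
            sig_rows.append(
                {
                    "metabolite": met,
                    "feature_group": group,
                    "point_ev": boot.point_ev,
                    "ci_low": boot.ci_low,
                    "ci_high": boot.ci_high,
                    "p_value": boot.p_value,
                    "significant": boot.significant,
                }
            )
            if spec.is_tree_ensemble:
                attributions.append(res.attribution())
        mean_ev[group] = pd.Series(group_ev)
        if attributions:
            long = pd.concat(
                [
                    a.table.assign(metabolite=a.metabolite, feature=a.table.index)
                    for a in attributions
                ],
                ignore_index=True,
            )[["metabolite", "feature", "mean_abs_shap", "spearman_sign", "directional_mean_abs_shap"]]
            long.to_csv(
                out / f"attribution_{group}.tsv", sep="\t", index=False, float_format=FLOAT_FMT
            )
            write_table(
                attribution_matrix(attributions), out / f"attribution_matrix_{group}.tsv",
                index_label="metabolite",
            )
    stages.append("model")
    stages.append("bootstrap")
    stages.append("attribution")

    pd.DataFrame(score_rows).to_csv(
        out / "cv_scores.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    pd.DataFrame(sig_rows).to_csv(
        out / "bootstrap_significance.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    # descriptive layer: physio-metabolite Spearman screen, cluster map on
    # the configured group's mean EV, total-acid ANOVA across sample clusters
    rho, pval = spearman_association(
        pd.concat([tables.physio, tables.aging_year.to_frame("aging_year")], axis=1),
        prep.metabolites,
    )
    write_table(rho, out / "spearman_rho.tsv", index_label="index")
    write_table(pval, out / "spearman_p.tsv", index_label="index")
    report: dict = {}
    try:
        cmap = cluster_metabolite_map(
            prep.metabolites[met_names],
            mean_ev[config.cluster_feature_group],
            threshold=config.ev_threshold,
        )
        cmap.metabolite_labels.rename("MC").rename_axis("metabolite").to_csv(
            out / "metabolite_clusters.tsv", sep="\t"
        )
        cmap.sample_labels.rename("SC").rename_axis("sample_id").to_csv(
            out / "sample_clusters.tsv", sep="\t"
        )
        (out / "metabolite_dendrogram.nwk").write_text(
            linkage_to_newick(cmap.metabolite_linkage, cmap.retained) + "\n"
        )
        (out / "sample_dendrogram.nwk").write_text(
            linkage_to_newick(cmap.sample_linkage, list(cmap.sample_labels.index)) + "\n"
        )
        f, p = anova_by_cluster(tables.physio["total_acid"], cmap.sample_labels)
        report["total_acid_anova"] = {"F": f, "p": p}
        report["n_well_predicted"] = len(cmap.retained)
    except ValueError as exc:  # e.g. nothing clears the EV threshold
        report["cluster_map_skipped"] = str(exc)
    stages.append("report")

    manifest = {
        "package": "brewlink",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": stages,
        "dropped": {
            "metabolites": prep.dropped_metabolites,
            "species": prep.dropped_species,
            "genera": prep.dropped_genera,
        },
        "report": report,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
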