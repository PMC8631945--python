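"""End-to-end orchestration: geometry -> MA -> polynomial/AIC -> PCA -> K -> pPCA.

`run_pipeline` validates its inputs up front (nothing is written on
failure), executes every stage, and leaves a self-contained output
directory: per-stage CSV tables, a JSON report recording every decision
(selected order, seeds, policies), and the two standard figures.  Given the
same configuration and seed the CSV outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import functional, mechanics, phylo
from .landmarks import (composite_representation, read_landmarks_csv,
                        reflect_to_reference)

logger = logging.getLogger("gnathomech")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    Exactly one of ``landmarks`` (long-format landmark CSV) or ``curves``
    (specimen_id, s, ma table) must be given.  ``fossil_fragments`` points
    at a landmark CSV holding distorted fragments of one fossil, combined
    into a composite before MA extraction.  A seed is mandatory whenever
    permutations are requested.
    """

    outdir: str
    landmarks: str | None = None
    curves: str | None = None
    fossil_fragments: str | None = None
    tree: str | None = None
    metadata: str | None = None
    n_points: int = 100
    candidate_orders: list[int] = field(default_factory=lambda: list(range(1, 9)))
    descriptor_policy: str = "exclude_intercept"
    pca_mode: str = "covariance"
    n_permutations: int = 9999
    seed: int | None = None
    skip_phylo: bool = False
    fossil_id: str = "CFMR"
    reference_side: str = "left"
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ValidationCheck:
    name: str
    status: str  # ok | warning | failure
    message: str = ""


@dataclass
class ValidationReport:
    checks: list[ValidationCheck] = field(default_factory=list)

    def add(self, name: str, status: str, message: str = "") -> None:
        self.checks.append(ValidationCheck(name, status, message))

    @property
    def passed(self) -> bool:
        return all(c.status != "failure" for c in self.checks)

    @property
    def failures(self) -> list[ValidationCheck]:
        return [c for c in self.checks if c.status == "failure"]

    @property
    def warnings(self) -> list[ValidationCheck]:
        return [c for c in self.checks if c.status == "warning"]

    def to_dict(self) -> dict:
        return {"passed": self.passed,
                "checks": [dataclasses.asdict(c) for c in self.checks]}


def _load_curves(config: RunConfig):
    """Load or compute the MA curves declared by the configuration."""
    curves = []
    if config.curves:
        curves.extend(mechanics.ma_from_curve_table(config.curves))
    if config.landmarks:
        configs = read_landmarks_csv(config.landmarks)
        curves.extend(mechanics.curves_from_configs(configs,
                                                    n_points=config.n_points))
    if config.fossil_fragments:
        fragments = read_landmarks_csv(config.fossil_fragments)
        fragments = [reflect_to_reference(f, config.reference_side)
                     if f.side else f for f in fragments]
        cfmr = composite_representation(fragments, specimen_id=config.fossil_id)
        logger.info("composite %s built from %d fragments",
                    config.fossil_id, len(fragments))
        curves.append(mechanics.ma_curve(
            mechanics.lever_geometry_from_landmarks(cfmr),
            n_points=config.n_points))
    return curves


def validate_inputs(config: RunConfig) -> ValidationReport:
    """Schema- and cross-check every input without modifying anything."""
    report = ValidationReport()
    if not (config.landmarks or config.curves):
        report.add("inputs", "failure",
                   "neither a landmark table nor a curve table was given")
        return report
    if config.n_permutations and not config.skip_phylo and config.seed is None:
        report.add("seed", "failure",
                   "a seed is required when permutations are requested")

    specimen_ids: list[str] = []
    try:
        curves = _load_curves(config)
        specimen_ids = [c.specimen_id for c in curves]
        report.add("curves", "ok", f"{len(curves)} MA curves loaded")
    except (OSError, ValueError) as exc:
        report.add("curves", "failure", str(exc))

    meta = None
    if config.metadata:
        try:
            meta = pd.read_csv(config.metadata)
            if "specimen_id" not in meta.columns:
                raise ValueError("metadata lacks a specimen_id column")
            report.add("metadata", "ok", f"{len(meta)} metadata rows")
        except (OSError, ValueError) as exc:
            meta = None
            report.add("metadata", "failure", str(exc))
    if meta is not None and specimen_ids:
        missing = sorted(set(specimen_ids) - set(meta["specimen_id"].astype(str)))
        if missing:
            report.add("metadata_coverage", "failure",
                       f"specimens without a metadata row: {missing}")
        else:
            report.add("metadata_coverage", "ok", "")

    if not config.skip_phylo:
        if not config.tree:
            report.add("tree", "failure",
                       "a tree is required unless skip_phylo is set")
        else:
            try:
                tree = phylo.read_newick(config.tree)
                report.add("tree", "ok", f"{tree.n_tips} tips")
                if specimen_ids:
                    tips = set(tree.tip_labels)
                    ids = set(specimen_ids)
                    extra = sorted(tips - ids)
                    missing = sorted(ids - tips)
                    if extra:
                        report.add("tree_extra_tips", "warning",
                                   f"tips without specimens (pruned): {extra}")
                    if missing:
                        report.add("tree_missing_tips", "failure",
                                   f"specimens missing from the tree: {missing}")
            except (OSError, ValueError) as exc:
                report.add("tree", "failure", str(exc))
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write tables, figures and a JSON report.

    Raises ``ValueError`` before writing anything when validation fails.
    Returns the report dictionary (also written as ``report.json``).
    """
    validation = validate_inputs(config)
    if not validation.passed:
        msgs = "; ".join(f"{c.name}: {c.message}" for c in validation.failures)
        raise ValueError(f"input validation failed — {msgs}")
    for warning in validation.warnings:
        logger.warning("%s: %s", warning.name, warning.message)

    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    report: dict = {"config": config.to_dict(),
                    "validation": validation.to_dict(),
                    "artifacts": {}}

    def _write(df: pd.DataFrame, name: str) -> None:
        path = os.path.join(outdir, name)
        df.to_csv(path, index=False)
        report["artifacts"][name] = path

    diet: dict[str, str] = {}
    if config.metadata:
        meta = pd.read_csv(config.metadata)
        if "diet" in meta.columns:
            diet = dict(zip(meta["specimen_id"].astype(str), meta["diet"]))

    # --- stage 1: MA curves -------------------------------------------------
    curves = _load_curves(config)
    _write(mechanics.curves_to_table(curves), "ma_curves.csv")
    logger.info("stage ma: %d curves at n_points=%d", len(curves), config.n_points)

    # --- stage 2: polynomial order selection and coefficients ---------------
    best_order, aic_table = functional.select_order_by_aic(
        curves, config.candidate_orders)
    logger.info("stage fit: selected order %d by pooled AIC", best_order)
    _write(pd.DataFrame({"order": list(aic_table),
                         "aic": [aic_table[q] for q in aic_table]}),
           "aic_table.csv")
    fits = [functional.fit_polynomial(c, best_order) for c in curves]
    space = functional.build_coefficient_matrix(fits, config.descriptor_policy)
    coef_cols = [f"beta{j}" for j in
                 range(0 if config.descriptor_policy == "include_intercept" else 1,
                       best_order + 1)]
    _write(pd.DataFrame(space.coefficient_matrix, columns=coef_cols)
           .assign(specimen_id=space.specimen_ids)
           [["specimen_id", *coef_cols]], "coefficients.csv")
    report["selected_order"] = best_order
    report["aic"] = {str(q): aic_table[q] for q in aic_table}
    report["descriptor_policy"] = config.descriptor_policy

    # --- stage 3: ordinary PCA ----------------------------------------------
    space = functional.pca(space,
                           scale_to_correlation=config.pca_mode == "correlation")
    n_pc = space.pc_scores.shape[1]
    pc_cols = [f"PC{i + 1}" for i in range(n_pc)]
    _write(pd.DataFrame(space.pc_scores, columns=pc_cols)
           .assign(specimen_id=space.specimen_ids)[["specimen_id", *pc_cols]],
           "pca_scores.csv")
    _write(pd.DataFrame(space.pc_loadings, columns=coef_cols)
           .assign(component=pc_cols)[["component", *coef_cols]],
           "pca_loadings.csv")
    _write(pd.DataFrame({"component": pc_cols,
                         "eigenvalue": space.eigenvalues,
                         "variance_explained_pct": space.variance_explained}),
           "pca_variance.csv")
    report["pca_variance_explained_pct"] = [float(v) for v in space.variance_explained]

    # --- stage 4: phylogenetic signal and pPCA -------------------------------
    if not config.skip_phylo:
        tree = phylo.read_newick(config.tree)
        extra = set(tree.tip_labels) - set(space.specimen_ids)
        if extra:
            pruned = tree.tree.extract_tree_without_taxa_labels(sorted(extra))
            tree = phylo.Phylogeny(pruned)
        order = [space.specimen_ids.index(lab) for lab in tree.tip_labels]
        X = space.coefficient_matrix[order]

        k_by_descriptor = {col: phylo.blomberg_k(X[:, j], tree)
                           for j, col in enumerate(coef_cols)}
        signal = phylo.permutation_test("K_mult", X, tree,
                                        n_permutations=config.n_permutations,
                                        seed=config.seed)
        logger.info("stage signal: K_mult=%.5f p=%.5g (%d permutations, seed %d)",
                    signal.observed, signal.p_value, signal.n_permutations,
                    signal.seed)
        report["signal"] = {
            "k_mult": signal.observed,
            "p_value": signal.p_value,
            "n_permutations": signal.n_permutations,
            "seed": signal.seed,
            "k_univariate": {k: float(v) for k, v in k_by_descriptor.items()},
        }
        with open(os.path.join(outdir, "signal.json"), "w") as fh:
            json.dump(report["signal"], fh, indent=2, sort_keys=True)
        report["artifacts"]["signal.json"] = os.path.join(outdir, "signal.json")

        ppca = phylo.phylogenetic_pca(X, tree)
        p_cols = [f"PC{i + 1}" for i in range(ppca.scores.shape[1])]
        _write(pd.DataFrame(ppca.scores, columns=p_cols)
               .assign(specimen_id=tree.tip_labels)[["specimen_id", *p_cols]],
               "ppca_scores.csv")
        _write(pd.DataFrame(ppca.loadings, columns=coef_cols)
               .assign(component=p_cols)[["component", *coef_cols]],
               "ppca_loadings.csv")
        _write(pd.DataFrame({"component": p_cols,
                             "eigenvalue": ppca.eigenvalues,
                             "variance_explained_pct": ppca.variance_explained}),
               "ppca_variance.csv")
        report["ppca_variance_explained_pct"] = [
            float(v) for v in ppca.variance_explained]

    # --- figures -------------------------------------------------------------
    if config.make_plots:
        from . import plots
        plots.plot_ma_curves(curves, diet, os.path.join(outdir, "ma_curves.png"),
                             fossil_id=config.fossil_id)
        plots.plot_pc_scatter(space.pc_scores, space.specimen_ids, diet,
                              space.variance_explained,
                              os.path.join(outdir, "pca_scatter.png"),
                              fossil_id=config.fossil_id, title="PCA")
        report["artifacts"]["ma_curves.png"] = os.path.join(outdir, "ma_curves.png")
        report["artifacts"]["pca_scatter.png"] = os.path.join(outdir, "pca_scatter.png")

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
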