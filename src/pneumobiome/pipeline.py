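"""End-to-end orchestration: simulate -> diversity -> cluster -> associate.

A single :class:`RunConfig` (YAML-loadable) drives every stage; each
stage writes its outputs (TSV/CSV/JSON) into the run directory, logs
its seed and settings into ``run_log.json``, and a ``summary.json``
bundles the headline numbers (cluster sizes, best K, concordance,
per-covariate R^2, per-analyte explained %).  Reruns with the same
config and seed reproduce byte-identical outputs.  Any stage failure
halts the pipeline with the stage name; partial outputs are retained.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, cohort, diversity, dmm, io_formats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for a full pipeline run (defaults mirror the analysis plan)."""

    out_dir: str = "pneumobiome_run"
    seed: int = 0
    # simulation (None -> package defaults); alternatively input paths
    simulate: dict = field(default_factory=dict)
    input_paths: dict | None = None  # counts/tree/metadata/panel files
    # community metrics
    rarefaction_depth: int | None = None  # None -> min retained depth
    rarefaction_floor: int = 1000
    unifrac_weighted: bool = True
    unifrac_normalized: bool = True
    # DMM
    k_range: tuple = (1, 2, 3, 4)
    dmm_seeds: int = 3
    dmm_restarts: int = 5
    n_folds: int = 10
    # variance explained
    n_axes: int = 4
    varexp_alpha: float = 0.2
    varexp_perm: int = 999
    # PERMANOVA
    permanova_perm: int = 9999
    permanova_terms: tuple = ("group", "age", "sex", "prior_antibiotics")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise io_formats.ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("n_axes", "varexp_perm", "permanova_perm", "n_folds"):
            if getattr(cfg, name) < 1:
                raise io_formats.ValidationError(f"config field {name} must be >= 1")
        if not 0.0 <= cfg.varexp_alpha <= 1.0:
            raise io_formats.ValidationError("varexp_alpha must be in [0, 1]")
        return cfg


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and return the summary dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: list[dict] = []
    summary: dict = {"seed": config.seed}

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:
                run_log.append({"stage": name, "status": "failed", "error": str(exc)})
                _write_json(run_log, out / "run_log.json")
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            run_log.append({"stage": name, "status": "ok",
                            "seconds": round(time.time() - t0, 2)})
            return result
        return wrap

    # --- stage 1: inputs -------------------------------------------------
    def _simulate():
        sim_cfg = cohort.CohortConfig(seed=config.seed, **config.simulate)
        data = cohort.generate_cohort(sim_cfg)
        for tp, table in data.counts.items():
            io_formats.write_count_table(table, out / f"counts_{tp}.tsv")
        io_formats.write_tree_newick(data.tree, out / "tree.nwk")
        io_formats.write_metadata(data.metadata, out / "metadata.csv")
        for tp, panel in data.responses.items():
            io_formats.write_response_panel(panel, out / f"panel_{tp}.csv",
                                            out / f"analytes_{tp}.csv")
        data.ground_truth.components.rename("component").rename_axis(
            "sample_id").to_csv(out / "ground_truth.tsv", sep="\t")
        return data

    data = stage("simulate")(_simulate)

    # --- stage 2: alpha/beta diversity -----------------------------------
    def _diversity():
        frames = []
        for tp, table in data.counts.items():
            frames.append(pd.DataFrame({
                "shannon": diversity.shannon_index(table),
                "observed_richness": diversity.observed_richness(table),
                "timepoint": tp,
            }))
        alpha = pd.concat(frames)
        alpha.rename_axis("sample_id").to_csv(out / "alpha_diversity.tsv", sep="\t")
        # admission patients + controls carry the CAP-vs-control contrast
        adm, ctl = data.counts["admission"], data.counts["control"]
        pooled = io_formats.CountTable(
            adm.sample_ids + ctl.sample_ids, list(adm.taxon_ids),
            np.vstack([adm.counts, ctl.counts]))
        dmat = diversity.unifrac(pooled, data.tree,
                                 weighted=config.unifrac_weighted,
                                 normalized=config.unifrac_normalized)
        diversity.write_distance_matrix(dmat, out / "unifrac_admission_controls.tsv")
        return dmat

    dmat = stage("diversity")(_diversity)

    # --- stage 3: PERMANOVA variance partition ----------------------------
    def _permanova():
        part = association.variance_partition(
            dmat, data.metadata.select_samples(dmat.sample_ids),
            config.permanova_terms, n_perm=config.permanova_perm,
            seed=config.seed + 1)
        part.to_csv(out / "permanova_partition.tsv", sep="\t", index=False)
        summary["permanova"] = part.set_index("covariate")["r2"].round(6).to_dict()
        return part

    stage("permanova")(_permanova)

    # --- stage 4: DMM clustering ------------------------------------------
    assignments = {}

    def _dmm():
        summary["dmm"] = {}
        for tp in ("admission", "month"):
            table = data.counts[tp]
            depth = config.rarefaction_depth or diversity.default_rarefaction_depth(
                table, config.rarefaction_floor)
            rare = diversity.rarefy(table, depth, seed=config.seed + 2)
            best_k, evidence = dmm.select_k(rare, config.k_range,
                                            config.dmm_seeds,
                                            n_restarts=config.dmm_restarts)
            model = dmm.fit_dmm(rare, best_k, seed=config.seed + 3,
                                n_restarts=config.dmm_restarts)
            assign = dmm.hard_assignment(model)
            conc = dmm.reclustering_concordance(rare, best_k,
                                                n_folds=config.n_folds,
                                                seed=config.seed + 4,
                                                n_restarts=config.dmm_restarts)
            assignments[tp] = assign
            pd.DataFrame({"sample_id": assign.sample_ids,
                          "cluster": assign.labels,
                          "posterior": assign.probabilities}).to_csv(
                out / f"dmm_clusters_{tp}.tsv", sep="\t", index=False)
            sizes = pd.Series(assign.labels).value_counts().sort_index()
            summary["dmm"][tp] = {
                "rarefaction_depth": depth,
                "best_k": int(best_k),
                "evidence": {int(k): round(v, 2) for k, v in evidence.items()},
                "cluster_sizes": {int(k): int(v) for k, v in sizes.items()},
                "concordance_pct": round(conc.concordance_pct, 2),
                "n_assignments": conc.n_assignments,
                "n_discordant": conc.n_discordant,
            }

    stage("dmm")(_dmm)

    # --- stage 5: microbiota-to-cytokine variance explained ---------------
    varexp = {}

    def _varexp():
        summary["variance_explained"] = {}
        for tp in ("admission", "month"):
            dm_tp = diversity.unifrac(data.counts[tp], data.tree,
                                      weighted=config.unifrac_weighted,
                                      normalized=config.unifrac_normalized)
            res = association.cytokine_variance_explained(
                dm_tp, data.responses[tp], n_axes=config.n_axes,
                alpha=config.varexp_alpha, n_perm=config.varexp_perm,
                seed=config.seed + 5)
            varexp[tp] = res
            res.table.to_csv(out / f"variance_explained_{tp}.tsv", sep="\t")
            pct = res.explained_pct
            summary["variance_explained"][tp] = {
                "median_pct": round(float(pct.median()), 3),
                "iqr_pct": [round(float(pct.quantile(q)), 3) for q in (0.25, 0.75)],
                "max_pct": round(float(pct.max()), 3),
            }
        comp = association.compare_explained(varexp["admission"], varexp["month"])
        summary["variance_explained"]["admission_vs_month_p"] = round(comp["p"], 5)

    stage("varexp")(_varexp)

    # --- stage 6: cluster comparisons and butyrate associations -----------
    def _associate():
        reference = cohort.default_butyrate_reference()
        for tp in ("admission", "month"):
            score = association.butyrate_score(data.counts[tp], reference)
            score.scores.rename_axis("sample_id").to_csv(
                out / f"butyrate_score_{tp}.tsv", sep="\t")
            corr = association.spearman_association(score, data.responses[tp])
            corr.to_csv(out / f"spearman_butyrate_{tp}.tsv", sep="\t")
            if tp in assignments and len(set(assignments[tp].labels)) == 2:
                grp = association.adjusted_group_compare(
                    data.responses[tp], assignments[tp], data.metadata)
                grp.table.to_csv(out / f"cluster_comparison_{tp}.tsv", sep="\t")

    stage("associate")(_associate)

    _write_json(run_log, out / "run_log.json")
    _write_json(summary, out / "summary.json")
    return summary
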