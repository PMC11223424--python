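"""End-to-end orchestration: load-or-simulate, rarefy, diversity, discriminant
taxa, CAG construction, sample grouping, exclusion re-analysis, clinical
associations, and a machine-readable report.

Every stochastic stage draws its seed deterministically from the master seed
(fixed spawn keys), so stages can be re-run in isolation and two runs with
the same master seed produce byte-identical report payloads.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cag as cagmod
from . import clinical_assoc, data_io, diff_abundance, diversity, synthetic_data

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"

# fixed per-stage seed offsets (spawn keys) off the master seed
STAGE_SEEDS = {"simulate": 1, "rarefy": 2, "permanova": 3, "lefse": 4}


def stage_seed(master_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(STAGE_SEEDS[stage],))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class PipelineConfig:
    """Defaults match the reference analysis parameters: rarefaction depth
    16,864, 0.1% genus filter in both tissues, k=4 CAGs, g=6 sample groups,
    LDA threshold 3.5, 999 permutations."""

    table_path: str | None = None
    metadata_path: str | None = None
    simulation: synthetic_data.SimulationConfig | None = None
    rarefaction_depth: int = 16_864
    filter_threshold: float = 0.001
    filter_mode: str = "both_groups"
    genus_distance_mode: str = "spearman"
    k: int = 4
    g: int = 6
    lda_threshold: float = 3.5
    n_permutations: int = 999
    clinical_variables: tuple[str, ...] = ("microsatellite", "stage", "ki67")
    markers: tuple[str, ...] = data_io.MARKERS
    exclude_group: str | int = "auto"
    master_seed: int = 0
    out_dir: str | None = None


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (pd.Series,)):
        return _jsonable(obj.to_dict())
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _contrast_rows(results) -> list[dict]:
    return [{"feature": r.feature, "test": r.test, "statistic": r.statistic,
             "p_value": r.p_value, "medians_percent": r.group_medians, "n": r.n}
            for r in results]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report dict (and writes the
    report bundle if ``cfg.out_dir`` is set)."""
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "config": _jsonable(dataclasses.asdict(cfg)),
                    "seeds": {s: stage_seed(cfg.master_seed, s) for s in STAGE_SEEDS}}
    stage = "load"
    try:
        if cfg.simulation is not None:
            stage = "simulate"
            sim_cfg = dataclasses.replace(cfg.simulation,
                                          seed=stage_seed(cfg.master_seed, "simulate"))
            ds = synthetic_data.simulate(sim_cfg)
            table, meta = ds.table, ds.meta
            report["input"] = {"source": "simulation",
                               "n_samples": len(table.samples),
                               "n_genera": len(table.taxa)}
        else:
            if cfg.table_path is None or cfg.metadata_path is None:
                raise data_io.DataError("either simulation or table+metadata paths required")
            table = data_io.read_abundance_table(cfg.table_path)
            meta = data_io.read_metadata(cfg.metadata_path, table)
            ds = None
            report["input"] = {"source": str(cfg.table_path),
                               "n_samples": len(table.samples),
                               "n_genera": len(table.taxa)}
        logger.info("input: %d genera x %d samples", len(table.taxa), len(table.samples))

        stage = "rarefy"
        rare = data_io.rarefy(table, cfg.rarefaction_depth,
                              stage_seed(cfg.master_seed, "rarefy"))
        report["rarefaction"] = {"depth": cfg.rarefaction_depth,
                                 "n_retained": len(rare.samples),
                                 "n_dropped": len(table.samples) - len(rare.samples)}
        logger.info("rarefaction at %d: %d samples retained", cfg.rarefaction_depth,
                    len(rare.samples))
        meta_r = meta.loc[rare.samples]

        stage = "alpha_diversity"
        alpha = diversity.alpha_table(rare)
        tissue = meta_r["tissue"]
        alpha_contrasts = {}
        for ix in diversity.ALPHA_INDICES:
            res = diff_abundance.mann_whitney(
                alpha.loc[tissue == "TT", ix], alpha.loc[tissue == "NT", ix], feature=ix)
            alpha_contrasts[ix] = {
                "p_value": res.p_value,
                "median_TT": float(alpha.loc[tissue == "TT", ix].median()),
                "median_NT": float(alpha.loc[tissue == "NT", ix].median())}
        report["alpha_diversity"] = alpha_contrasts

        stage = "beta_diversity"
        rel = data_io.to_relative(rare)
        dm = diversity.bray_curtis(rel)
        ord_res = diversity.pcoa(dm, n_axes=2)
        perm = diversity.permanova(dm, tissue.to_numpy(), n_perm=cfg.n_permutations,
                                   seed=stage_seed(cfg.master_seed, "permanova"))
        report["permanova"] = {"pseudo_F": perm.pseudo_F, "p_value": perm.p_value,
                               "n_permutations": perm.n_permutations,
                               "exhaustive": perm.exhaustive}
        report["pcoa"] = {"proportion_explained_axis1":
                          float(ord_res.proportion_explained[0]),
                          "n_negative_eigenvalues": len(ord_res.negative_eigenvalues)}

        stage = "lefse"
        lefse = diff_abundance.lefse_score(
            rel, tissue.to_numpy(), threshold=cfg.lda_threshold,
            seed=stage_seed(cfg.master_seed, "lefse"))
        passing = [r for r in lefse if r.passes]
        report["lefse"] = {"threshold": cfg.lda_threshold,
                           "n_passing": len(passing),
                           "passing": [{"feature": r.feature,
                                        "enriched_class": r.enriched_class,
                                        "lda_score": r.lda_score} for r in
                                       sorted(passing, key=lambda r: -r.lda_score)]}

        stage = "cag"
        model = cagmod.build_cag_model(rel, meta_r, k=cfg.k,
                                       threshold=cfg.filter_threshold,
                                       filter_mode=cfg.filter_mode,
                                       distance_mode=cfg.genus_distance_mode)
        logger.info("%d genera retained by the %.2g%% filter; %d CAGs",
                    len(model.assignment), cfg.filter_threshold * 100, cfg.k)
        profiles = cagmod.cag_profiles(rel, model)
        grouping = cagmod.cluster_samples(profiles, cfg.g, meta_r)
        report["cag"] = {"k": cfg.k, "n_retained_genera": len(model.assignment),
                         "membership": {c: sorted(model.members(c)) for c in model.cags},
                         "sizes": {c: len(model.members(c)) for c in model.cags}}
        report["sample_groups"] = {
            "g": cfg.g,
            "composition": {str(i): {"TT": int(grouping.composition.loc[i, "TT"]),
                                     "NT": int(grouping.composition.loc[i, "NT"])}
                            for i in grouping.composition.index}}

        stage = "cag_contrasts"
        contrasts = cagmod.compare_cag_abundance(profiles, meta_r)
        report["cag_contrasts"] = _contrast_rows(contrasts)

        stage = "exclusion"
        if cfg.exclude_group == "auto":
            excl = cagmod.pick_dominant_group(profiles, grouping)
        else:
            excl = int(cfg.exclude_group) if cfg.exclude_group is not None else None
        if excl is not None:
            post, corr = cagmod.exclude_group_and_recompute(profiles, grouping, excl, meta_r)
            report["exclusion"] = {"excluded_group": excl,
                                   "contrasts": _contrast_rows(post),
                                   "cag_correlation": _jsonable(corr.round(6).to_dict())}
        else:
            report["exclusion"] = {"excluded_group": None,
                                   "note": "no group exceeded the dominance heuristic"}

        stage = "clinical"
        assoc = clinical_assoc.associate(profiles, meta_r,
                                         variables=cfg.clinical_variables,
                                         markers=cfg.markers)
        report["clinical_associations"] = _jsonable(assoc.to_dict(orient="records"))

        if ds is not None:
            stage = "truth_metrics"
            report["truth_metrics"] = _jsonable(synthetic_data.truth_metrics(
                ds, model, grouping, contrasts))
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        if cfg.out_dir:
            _write_report(report, None, None, None, cfg)
        raise

    if cfg.out_dir:
        _write_report(report, alpha, profiles, model, cfg, grouping=grouping,
                      assoc=assoc)
    return report


def report_json(report: dict) -> str:
    """Canonical report serialization (stable key order, no timestamps)."""
    return json.dumps(_jsonable(report), sort_keys=True, indent=2)


def _write_report(report, alpha, profiles, model, cfg, grouping=None, assoc=None):
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_json(report))
    (out / "config.yaml").write_text(
        yaml.safe_dump(_jsonable(dataclasses.asdict(cfg)), sort_keys=True))
    if alpha is not None:
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
    if profiles is not None:
        data_io.write_abundance_table(profiles, out / "cag_profiles.tsv")
    if model is not None:
        pd.Series(model.assignment, name="cag").rename_axis("genus").to_csv(
            out / "cag_membership.tsv", sep="\t")
        (out / "genus_dendrogram.nwk").write_text(model.dendrogram.to_newick())
    if grouping is not None:
        pd.Series(grouping.assignment, name="group").rename_axis("sample_id").to_csv(
            out / "sample_groups.tsv", sep="\t")
        grouping.composition.to_csv(out / "sample_group_composition.tsv", sep="\t")
    if assoc is not None and len(assoc):
        assoc.to_csv(out / "clinical_associations.tsv", sep="\t", index=False)
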