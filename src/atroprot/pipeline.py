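"""End-to-end orchestration of the analysis stages.

Stages run in dependency order on a synthetic study (or user tables):
quantification -> per-time differential statistics -> soft clustering ->
1D annotation enrichment -> random-forest atrogene scoring -> diglycine-site
analysis -> expression/synthesis integration.  All randomness derives from
one master seed; results are TSVs plus a JSON manifest, so identical
configurations produce byte-identical output directories.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as clus
from . import enrichment as enr
from . import forest as rf
from . import incorporation as inc
from . import integrate as integ
from . import quant
from . import sites as ubs
from . import stats
from . import synthetic as syn
from .tables import TimeProfileMatrix, write_results

logger = logging.getLogger(__name__)

ALL_STAGES = ("quantify", "test", "cluster", "enrich", "rf", "sites", "integrate")


@dataclass
class PipelineConfig:
    """Stage parameters; the defaults reproduce the reference parameter set
    (S0 = 0.1, permutation FDR 0.05, c = 6 clusters, data-estimated fuzzifier,
    50 forest repeats, candidate threshold 0.7, site fold cut 1.5)."""

    generator: syn.GeneratorConfig = field(default_factory=syn.GeneratorConfig)
    s0: float = 0.1
    target_fdr: float = 0.05
    n_perm: int | str = 250
    clusters: int = 6
    fuzzifier: float | str = "auto"
    min_membership: float = 0.5
    rf_n_repeats: int = 50
    rf_n_trees: int = 500
    rf_threshold: float = 0.7
    fold_cut: float = 1.5
    enrich_min_size: int = 10
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0

    def manifest_params(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = dataclasses.asdict(self.generator)
        d["generator"]["templates"] = {k: list(v) for k, v in
                                       self.generator.templates.items()}
        return d


def demo_config(seed: int = 0) -> PipelineConfig:
    """A small configuration for the one-command synthetic demo."""
    gen = syn.GeneratorConfig(n_proteins=300, n_atrogene_up=10, n_atrogene_down=8,
                              seed=seed)
    return PipelineConfig(generator=gen, rf_n_repeats=5, rf_n_trees=100, seed=seed)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns the in-memory results.

    Each stage writes its result tables under *out_dir*; a failing stage
    aborts with its name in the raised error while earlier outputs remain on
    disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    seedseq = np.random.SeedSequence(cfg.seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(ALL_STAGES, seedseq.spawn(len(ALL_STAGES)))}
    results: dict = {}
    tables: dict[str, pd.DataFrame] = {}

    expr_table, expr_design, truth = syn.generate_expression_study(cfg.generator)
    pulse_table, pulse_design, truth = syn.generate_pulse_study(cfg.generator, truth)
    site_table = syn.generate_site_study(cfg.generator, expr_table, truth)
    annotations = syn.generate_annotations(cfg.generator, truth)
    results["truth"] = truth
    tables["ground_truth_proteins"] = truth.proteins
    tables["ground_truth_delta"] = truth.delta

    def stage(name):
        return name in cfg.stages

    try:
        profiles = None
        fold = None
        if stage("quantify"):
            norm = quant.normalize_sample_ratios(expr_table)
            fold = quant.fold_change_table(norm)
            profiles = quant.build_time_profiles(fold)
            results["profiles"] = profiles
            results["normalization_offsets"] = norm.offsets
            tables["time_profiles"] = profiles.values
            tables["normalization_offsets"] = norm.offsets.rename("offset").to_frame()

        expr_tests = {}
        if stage("test") and fold is not None:
            for t in profiles.times:
                reps = fold[t]
                res = stats.permutation_fdr(reps, labels=None, s0=cfg.s0,
                                            target_fdr=cfg.target_fdr,
                                            n_perm=cfg.n_perm,
                                            seed=stage_seeds["test"])
                expr_tests[t] = res.table
                tables[f"expression_tests_day{t:g}"] = res.table
            results["expression_tests"] = expr_tests

        if stage("cluster") and profiles is not None:
            z = clus.zscore_profiles(profiles)
            m = (clus.estimate_fuzzifier(len(z), z.shape[1])
                 if cfg.fuzzifier == "auto" else float(cfg.fuzzifier))
            fc = clus.fuzzy_cmeans(z, c=cfg.clusters, m=m,
                                   seed=stage_seeds["cluster"])
            labels, unassigned = clus.assign_clusters(fc, cfg.min_membership)
            results["clustering"] = fc
            results["cluster_labels"] = labels
            results["fuzzifier"] = m
            tables["cluster_membership"] = fc.membership
            tables["cluster_labels"] = labels.to_frame()

        if stage("enrich") and profiles is not None:
            per_time, score_matrix = enr.enrichment_over_time(
                profiles, annotations, min_size=cfg.enrich_min_size)
            results["enrichment"] = per_time
            tables["enrichment_scores"] = score_matrix
            for t, df in per_time.items():
                tables[f"enrichment_day{t:g}"] = df

        if stage("rf") and profiles is not None:
            feats = rf.prepare_features(profiles.values)
            classes = rf.TrainingClasses(set(truth.atrogene_ids(1)) & set(feats.index),
                                         set(truth.atrogene_ids(2)) & set(feats.index))
            scores = rf.train_scoring_ensemble(
                classes, feats, n_repeats=cfg.rf_n_repeats,
                n_trees=cfg.rf_n_trees, seed=stage_seeds["rf"])
            candidates = rf.call_candidates(scores, cfg.rf_threshold)
            results["rf_scores"] = scores
            results["rf_candidates"] = candidates
            tables["rf_scores"] = scores.table
            tables["rf_candidates"] = candidates

        incorp = None
        if stage("test"):
            incorp = inc.differential_incorporation(
                pulse_table, s0=cfg.s0, alpha=cfg.target_fdr,
                n_perm=cfg.n_perm, seed=stage_seeds["test"])
            results["incorporation"] = incorp
            for t, df in incorp["per_time"].items():
                tables[f"incorporation_tests_day{t:g}"] = df
            tables["incorporation_auc"] = incorp["profiles"].auc

        if stage("sites") and profiles is not None:
            norm_sites = ubs.normalize_site_ratios(site_table, profiles)
            flagged = ubs.regulated_sites(norm_sites.raw, site_table.design,
                                          s0=cfg.s0, target_fdr=cfg.target_fdr,
                                          fold_cut=cfg.fold_cut, n_perm=cfg.n_perm,
                                          seed=stage_seeds["sites"])
            hist, summary = ubs.sites_per_protein(site_table)
            results["sites"] = {"normalized": norm_sites, "flagged": flagged,
                                "histogram": hist, "summary": summary}
            tables["site_histogram"] = hist.to_frame()
            for t, df in flagged.items():
                tables[f"site_tests_day{t:g}"] = df

        if stage("integrate") and expr_tests and incorp is not None:
            shared_times = sorted(set(expr_tests) & set(incorp["per_time"]))
            sectors = {}
            for t in shared_times:
                sectors[t] = integ.classify_sectors(expr_tests[t],
                                                    incorp["per_time"][t])
                tables[f"sectors_day{t:g}"] = sectors[t]
            results["sectors"] = sectors
            norm = quant.normalize_sample_ratios(expr_table)
            results["qc"] = integ.qc_summary(norm.log2_lh)
            tables["qc_correlation"] = results["qc"].correlation
            tables["qc_pca"] = results["qc"].pca
    except Exception as err:
        raise RuntimeError(f"pipeline stage failed: {err}") from err

    write_results(tables, out, manifest=cfg.manifest_params())
    results["out_dir"] = out
    return results
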