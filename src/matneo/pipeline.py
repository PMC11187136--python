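"""End-to-end orchestration of the maternal-neonatal analysis.

A single :class:`PipelineConfig` drives either a synthetic cohort or
user-supplied files through: filtering -> rarefaction -> diversity
summaries -> maternal factor network -> modules -> dyad A/B groupings ->
module-vs-microbiota battery (Mann-Whitney, marginal PERMANOVA, dbRDA)
-> differential abundance -> NICU odds ratios and random-forest risk
model. Every stage derives its own seed from the global seed XOR a
CRC32 of the stage name, so stages can be re-run in isolation; all
artifacts are tidy TSV/JSON, and a manifest records the config, seeds
and output hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations, cohort, diffabund, diversity, grouping, network, risk, tables
from .factors import FactorTable

log = logging.getLogger("matneo")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % 2**31


@dataclass
class PipelineConfig:
    """All thresholds and toggles of the pipeline in one place."""

    # inputs: either a synthetic cohort spec or paths to user data
    synthetic: cohort.SyntheticCohortSpec | None = None
    counts_path: str | None = None
    meta_path: str | None = None
    factors_path: str | None = None
    factor_types_path: str | None = None
    outcomes_path: str | None = None

    min_reads: int = 5000
    rarefaction_depth: int = 5000
    alpha: float = 0.05
    resolution: float = 0.7
    n_perm: int = 999
    mc_instances: int = 128
    min_pair_n: int = 10
    tsne_perplexity: float = 30.0
    rf_trees: int = 500
    rf_folds: int = 5
    rf_repeats: int = 10
    seed: int = 0

    stages: tuple = (
        "simulate", "filter", "diversity", "network", "modules",
        "associate", "diffabund", "nicu",
    )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw.get("synthetic"):
            syn = raw["synthetic"]
            syn["blocks"] = [cohort.BlockSpec(**b) for b in syn.get("blocks", [])]
            syn["effects"] = [cohort.EffectSpec(**e) for e in syn.get("effects", [])]
            if "sequencing_depth_range" in syn:
                syn["sequencing_depth_range"] = tuple(syn["sequencing_depth_range"])
            raw["synthetic"] = cohort.SyntheticCohortSpec(**syn)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the configured stages, writing artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stage_seeds": {}, "outputs": {}, "notes": []}
    config.to_yaml(outdir / "config.yaml")

    def save(df: pd.DataFrame, name: str, index_label="id"):
        path = outdir / name
        df.to_csv(path, sep="\t", index_label=index_label)
        manifest["outputs"][name] = hashlib.sha256(path.read_bytes()).hexdigest()
        return path

    # -- load or simulate --------------------------------------------------
    stage = "simulate"
    if config.synthetic is not None:
        seed = stage_seed(config.seed, stage)
        manifest["stage_seeds"][stage] = seed
        spec = config.synthetic
        factors = cohort.generate_factor_table(spec)
        counts = cohort.generate_microbiota(spec, factors)
        outcomes = cohort.generate_outcomes(spec, factors)
        factors.to_tsv(outdir / "factors.tsv", outdir / "factor_types.tsv")
        tables.write_counts(counts, outdir / "counts_raw.tsv", outdir / "sample_meta.tsv")
        save(outcomes, "outcomes.tsv", index_label="dyad_id")
    else:
        counts = tables.load_counts(config.counts_path, config.meta_path)
        factors = FactorTable.from_tsv(config.factors_path, config.factor_types_path)
        outcomes = pd.read_csv(config.outcomes_path, sep="\t", index_col="dyad_id")
    log.info("cohort: %d dyads, %d variables, %d samples",
             factors.n_dyads, len(factors.variables), counts.n_samples)

    # -- filter + rarefy ---------------------------------------------------
    seed = stage_seed(config.seed, "filter")
    manifest["stage_seeds"]["filter"] = seed
    filtered = tables.filter_samples(counts, min_reads=config.min_reads)
    filtered = tables.filter_taxa(filtered)
    # taxon filtering can pull sample totals back under the depth
    filtered = tables.filter_samples(filtered, min_reads=config.rarefaction_depth)
    rarefied = tables.rarefy(filtered, depth=config.rarefaction_depth, seed=seed)
    tables.write_counts(rarefied, outdir / "counts_rarefied.tsv", outdir / "sample_meta_kept.tsv")
    log.info("filtering kept %d/%d samples, %d/%d taxa",
             filtered.n_samples, counts.n_samples, filtered.n_taxa, counts.n_taxa)

    # -- per site/day-slot diversity summaries -----------------------------
    seed = stage_seed(config.seed, "diversity")
    manifest["stage_seeds"]["diversity"] = seed
    matched = tables.match_dyad_samples(rarefied)
    summaries: dict[tuple, pd.DataFrame] = {}
    distances: dict[tuple, object] = {}
    neo_sites = sorted(matched.meta.loc[matched.meta["role"] == "neonate", "site"].unique())
    for site in neo_sites:
        for slot in ("day0", "day1or2"):
            sel = matched.meta[(matched.meta["site"] == site) & (matched.meta["slot"] == slot)]
            if len(sel) < 8:
                continue
            sub = matched.subset_samples(sel.index)
            alpha = diversity.alpha_diversity(sub)
            dm = diversity.bray_curtis(sub)
            emb = diversity.tsne_embed(dm, seed=seed, perplexity=config.tsne_perplexity)
            summary = alpha.join(emb)
            summary.index = sel["subject_id"].to_numpy()
            summaries[(site, slot)] = summary
            distances[(site, slot)] = (dm, sel["subject_id"].to_numpy())
            save(summary, f"diversity_{site}_{slot}.tsv", index_label="dyad_id")
    if not summaries:
        raise RuntimeError("diversity stage produced no sample sets")

    # -- maternal factor network -------------------------------------------
    seed = stage_seed(config.seed, "network")
    manifest["stage_seeds"]["network"] = seed
    assocs, skipped = network.pairwise_associate(factors, min_n=config.min_pair_n)
    save(assocs, "factor_associations.tsv", index_label="pair_id")
    graph = network.build_network(assocs, alpha=config.alpha, nodes=factors.variables)
    modules = network.detect_modules(graph, resolution=config.resolution, seed=seed)
    centrality = network.betweenness(graph)
    nodes = pd.DataFrame({"module": modules, "betweenness": centrality})
    save(nodes, "factor_network_nodes.tsv", index_label="variable")
    network.write_graphml(graph, outdir / "factor_network.graphml")
    log.info("network: %d nodes, %d edges, %d modules (+catch-all)",
             graph.number_of_nodes(), graph.number_of_edges(), modules.attrs["n_modules"])

    # -- dyad A/B groupings per module --------------------------------------
    groupings = {}
    for mid in sorted(modules.unique()):
        module_vars = list(modules.index[modules == mid])
        if len(module_vars) < 1:
            continue
        dm = grouping.module_distance(factors, module_vars)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grp = grouping.cluster_dyads(dm)
        groupings[f"module_{mid}"] = grp.labels
    groupings = pd.DataFrame(groupings)
    groupings.index = list(factors.data.index)
    save(groupings, "dyad_groupings.tsv", index_label="dyad_id")
    indep = grouping.module_independence(groupings)
    save(indep, "module_independence.tsv", index_label="pair_id")

    # -- association battery -------------------------------------------------
    seed = stage_seed(config.seed, "associate")
    manifest["stage_seeds"]["associate"] = seed
    battery = []
    permanova_rows = []
    n_sig = 0
    for (site, slot), summary in summaries.items():
        res = associations.module_vs_summary(groupings, summary)
        res.insert(0, "site", site)
        res.insert(1, "slot", slot)
        battery.append(res)
        n_sig += int((res["p_adj"] <= config.alpha).sum())
        dm, subject_ids = distances[(site, slot)]
        from skbio import DistanceMatrix as _DM

        dm_d = _DM(dm.data, ids=[str(s) for s in subject_ids])
        avail = groupings.loc[[s for s in subject_ids if s in groupings.index]]
        usable = [c for c in avail.columns if avail[c].nunique() == 2]
        if usable and len(avail) == len(subject_ids):
            marg = associations.marginal_permanova_modules(
                dm_d, avail[usable], n_perm=config.n_perm, seed=seed
            )
            marg.insert(0, "site", site)
            marg.insert(1, "slot", slot)
            permanova_rows.append(marg)
            sig_modules = marg.loc[marg["p_value"] <= config.alpha, "module"]
            if len(sig_modules):
                ord_res = associations.dbrda(dm_d, avail[list(sig_modules)])
                ord_res.site_scores.to_csv(
                    outdir / f"dbrda_sites_{site}_{slot}.tsv", sep="\t", index_label="dyad_id"
                )
                ord_res.biplot_scores.to_csv(
                    outdir / f"dbrda_biplot_{site}_{slot}.tsv", sep="\t", index_label="constraint"
                )
    battery = pd.concat(battery, ignore_index=True)
    save(battery, "module_vs_summary.tsv", index_label="row")
    if permanova_rows:
        save(pd.concat(permanova_rows, ignore_index=True), "marginal_permanova.tsv", index_label="row")
    manifest["n_bh_significant_module_findings"] = n_sig

    # -- differential abundance: day0 vs day1or2 per site --------------------
    seed = stage_seed(config.seed, "diffabund")
    manifest["stage_seeds"]["diffabund"] = seed
    da_frames = []
    for site in neo_sites:
        sel = matched.meta[(matched.meta["site"] == site) & (matched.meta["slot"].isin(["day0", "day1or2"]))]
        if sel["slot"].nunique() < 2 or (sel["slot"].value_counts() < 2).any():
            continue
        sub = matched.subset_samples(sel.index)
        sub = tables.filter_taxa(sub)
        res = diffabund.aldex_like_test(
            sub, sel["slot"], n_instances=config.mc_instances, seed=seed
        )
        res.insert(0, "site", site)
        da_frames.append(res)
    if da_frames:
        save(pd.concat(da_frames), "differential_abundance.tsv", index_label="taxon")

    # -- NICU: odds ratios + random forest -----------------------------------
    seed = stage_seed(config.seed, "nicu")
    manifest["stage_seeds"]["nicu"] = seed
    nicu = outcomes["nicu"] if "nicu" in outcomes else outcomes.iloc[:, -1]
    strata = outcomes["preterm"].map({0: "term", 1: "preterm"}) if "preterm" in outcomes else None
    ors = associations.nicu_odds_ratios(groupings, nicu, strata=strata)
    save(ors, "nicu_odds_ratios.tsv", index_label="row")
    x = risk.encode_features(factors)
    try:
        report = risk.fit_rf(
            x, nicu, seed=seed, folds=config.rf_folds,
            repeats=config.rf_repeats, trees=config.rf_trees,
        )
        (outdir / "nicu_risk_model.json").write_text(json.dumps(report.to_dict(), indent=2))
        report.importances.to_frame().to_csv(outdir / "nicu_gini_importance.tsv", sep="\t", index_label="feature")
        manifest["auroc_cv"] = report.auroc_cv
    except ValueError as exc:
        manifest["notes"].append(f"risk model skipped: {exc}")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
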