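"""End-to-end pipeline orchestration with a reproducibility manifest.

Stage order: simulate (or load) inputs -> junction filtering/merging ->
novel-region derivation -> custom GFF3 + flattening -> bin/gene counting ->
DEU and DGE testing -> enrichment -> clinical statistics.  Each stage
persists its artifact and records row counts and thresholds in the manifest;
re-running with the same config and seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import asdict

import pandas as pd
import yaml

from . import __version__
from .annotation import flatten_annotation, write_custom_gff3
from .clinical import (
    SurvivalObservation,
    compare_groups,
    kaplan_meier,
    stratify_cohort,
)
from .counting import portion_meta, write_count_matrix
from .differential import (
    AnalysisThresholds,
    deu_test,
    dge_wald,
    exclude_genes,
    intersect_cohorts,
    pca_top_variable,
)
from .enrichment import permutation_test, rank_genes
from .junctions import derive_novel_regions, filter_and_merge
from .simulate import (
    SimulationConfig,
    make_annotation,
    make_toy_gene_sets,
    simulate_bin_counts,
    simulate_cohort,
    simulate_gene_counts,
    simulate_junctions,
    write_sj_dir,
)

logger = logging.getLogger(__name__)

_THRESHOLD_FIELDS = {f.name for f in dataclasses.fields(AnalysisThresholds)}
_SIM_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}
_TOP_KEYS = {"seed", "thresholds", "simulation", "junction_filter"}
_JF_KEYS = {"min_unique_reads", "min_samples", "max_distance"}


def validate_config(path_or_dict) -> dict:
    """Load and normalize a YAML pipeline config.

    Unknown keys are rejected; threshold and simulation defaults are
    injected.  Returns a dict with ``seed``, ``thresholds``
    (:class:`AnalysisThresholds`), ``simulation`` (:class:`SimulationConfig`)
    and ``junction_filter`` sections.
    """
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    seed = int(raw.get("seed", 0))

    tdict = raw.get("thresholds", {}) or {}
    bad = set(tdict) - _THRESHOLD_FIELDS
    if bad:
        raise ValueError(f"unknown threshold key(s): {sorted(bad)}")
    thresholds = AnalysisThresholds(**tdict)

    sdict = dict(raw.get("simulation", {}) or {})
    bad = set(sdict) - _SIM_FIELDS
    if bad:
        raise ValueError(f"unknown simulation key(s): {sorted(bad)}")
    sdict.setdefault("seed", seed)
    for key, val in list(sdict.items()):
        if isinstance(val, list):
            sdict[key] = tuple(val)
    sim = SimulationConfig(**sdict)

    jf = dict(raw.get("junction_filter", {}) or {})
    bad = set(jf) - _JF_KEYS
    if bad:
        raise ValueError(f"unknown junction_filter key(s): {sorted(bad)}")
    jf.setdefault("min_unique_reads", 3)
    jf.setdefault("min_samples", 2)
    jf.setdefault("max_distance", 500)

    return {"seed": seed, "thresholds": thresholds, "simulation": sim,
            "junction_filter": jf}


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config, out_dir: str) -> dict:
    """Run the full synthetic-cohort pipeline and write artifacts + manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    cfg = config if isinstance(config, dict) and "thresholds" in config else (
        validate_config(config)
    )
    sim: SimulationConfig = cfg["simulation"]
    thr: AnalysisThresholds = cfg["thresholds"]
    jf = cfg["junction_filter"]
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "seed": cfg["seed"],
        "thresholds": asdict(thr),
        "junction_filter": jf,
        "stages": {},
        "files": {},
    }

    def record(stage: str, **info):
        logger.info("stage %s: %s", stage, info)
        manifest["stages"][stage] = info

    # 1. annotation
    gff = os.path.join(out_dir, "annotation.gff3")
    genes = make_annotation(sim, gff)
    record("annotation", n_genes=len(genes))

    # 2. junctions
    sj_dir = os.path.join(out_dir, "sj")
    per_sample, truth_junctions = simulate_junctions(sim, genes)
    write_sj_dir(per_sample, sj_dir)
    merged = filter_and_merge(
        per_sample, genes,
        min_unique_reads=jf["min_unique_reads"], min_samples=jf["min_samples"],
    )
    regions = derive_novel_regions(merged, genes, max_distance=jf["max_distance"])
    custom_gff = os.path.join(out_dir, "custom.gff3")
    write_custom_gff3(genes, regions, custom_gff)
    record(
        "junctions",
        n_merged=len(merged),
        n_novel_regions=len(regions),
        n_planted=len(truth_junctions),
    )

    # 3. flatten + bin counts
    portions = flatten_annotation(genes, regions)
    cm_bins, truth_bins = simulate_bin_counts(sim, portions, truth_junctions)
    bins_tsv = os.path.join(out_dir, "bin_counts.tsv")
    write_count_matrix(cm_bins, bins_tsv)
    record("counting", n_portions=len(portions), n_truth_bins=len(truth_bins))

    # 4. DEU
    deu = deu_test(
        cm_bins.counts,
        cm_bins.meta["group_id"],
        sim.condition,
        thresholds=thr,
        novelty=cm_bins.meta["novelty"],
    )
    deu.to_csv(os.path.join(out_dir, "deu_results.tsv"), sep="\t")
    n_sig = int(deu["significant"].sum())
    record("deu", n_tested=int(deu["p"].notna().sum()), n_significant=n_sig)

    # 5. DGE (+ exclusions on the annotation side)
    kept_genes = exclude_genes(genes)
    cm_genes, truth_de = simulate_gene_counts(sim)
    dge = dge_wald(cm_genes.counts, sim.condition, thresholds=thr)
    dge.to_csv(os.path.join(out_dir, "dge_results.tsv"), sep="\t")
    record(
        "dge",
        n_excluded_biotype=len(genes) - len(kept_genes),
        n_tested=int(dge["p"].notna().sum()),
        n_candidates=int(dge["candidate"].sum()),
    )

    # 6. enrichment
    sets = make_toy_gene_sets(truth_de, rng_seed=sim.seed)
    ranked = rank_genes(dge, min_mean_reads=thr.gsea_min_mean_reads)
    gsea = permutation_test(ranked, sets, n_perm=1000, seed=sim.seed)
    gsea.to_csv(os.path.join(out_dir, "gsea_results.tsv"), sep="\t")
    record("gsea", n_sets=len(gsea), n_sig=int((gsea["q"] <= thr.gsea_q_max).sum()))

    # 7. clinical
    clinical, truth_strata = simulate_cohort(sim, cutoff=thr.pfs_cutoff_months)
    clinical.to_csv(os.path.join(out_dir, "clinical.csv"))
    obs = {
        pid: SurvivalObservation(row.pfs_months, int(row.event))
        for pid, row in clinical.iterrows()
    }
    strata = stratify_cohort(obs, cutoff=thr.pfs_cutoff_months)
    km = kaplan_meier(obs.values())
    tab = clinical.assign(stratum=strata)
    ltd_cmp = compare_groups(tab, "ltd_mm")
    record(
        "clinical",
        n_patients=len(clinical),
        n_early=int((strata == "early").sum()),
        n_late=int((strata == "late").sum()),
        km_median=km["median"],
        ltd_p=ltd_cmp["p"],
    )

    for name in ("annotation.gff3", "custom.gff3", "bin_counts.tsv",
                 "deu_results.tsv", "dge_results.tsv", "gsea_results.tsv",
                 "clinical.csv"):
        manifest["files"][name] = _sha256(os.path.join(out_dir, name))

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
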