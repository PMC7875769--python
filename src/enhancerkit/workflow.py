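"""Configuration and end-to-end orchestration of the analysis chain.

``run_pipeline`` executes the stage sequence simulate -> qc -> enhancers
-> modules -> link -> gwas -> traits on a synthetic compendium, writes
every artifact as plain text under an output directory and returns a
manifest mapping each stage to its inputs, outputs (with SHA-256
digests), parameters and seed.  The manifest is byte-deterministic for
a fixed configuration; wall-clock runtimes are written to a separate
run log so re-runs of the same configuration produce identical
manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enhancers as enh_mod
from . import gwas as gwas_mod
from . import linking as link_mod
from . import synthdata, trackqc
from . import traits as traits_mod
from .tracks import sha256_file, write_tsv


@dataclass
class PipelineConfig:
    """Thresholds and sizes for one pipeline run.

    Stage thresholds default to the reference analysis values: signal
    cutoff 2 over the element +/- 100 bp, k modules, link-keep
    probability 5/7, 5-kb catalog pruning, 2.5-kb midpoint overlap, 100
    catalog shuffles, fixed-marginal permutations, cosine edge cutoff
    0.25.  All stage seeds derive from the single master seed.
    """

    seed: int = 0
    synth: dict = field(default_factory=dict)
    signal_threshold: float = 2.0
    flank_bp: int = 100
    k_modules: int = 6
    link_threshold: float = link_mod.KEEP_THRESHOLD
    prune_window_bp: int = 5_000
    overlap_radius_bp: int = 2_500
    n_shuffles: int = 100
    n_permutations: int = 10_000
    edge_threshold: float = 0.25
    alpha: float = 0.05
    stages: tuple = ("simulate", "qc", "enhancers", "modules", "link", "gwas", "traits")

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("signal_threshold", "flank_bp", "prune_window_bp",
                     "overlap_radius_bp", "n_shuffles", "n_permutations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def synth_config(self) -> synthdata.SynthConfig:
        return synthdata.SynthConfig(seed=self.seed, **self.synth)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _params_hash(params: dict) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the enabled stages in dependency order and write a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}
    runtimes: dict = {}
    state: dict = {}

    stage_fns = {
        "simulate": _stage_simulate, "qc": _stage_qc, "enhancers": _stage_enhancers,
        "modules": _stage_modules, "link": _stage_link, "gwas": _stage_gwas,
        "traits": _stage_traits,
    }
    for stage in config.stages:
        fn = stage_fns[stage]
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                outputs, params = fn(config, state, outdir)
            except Exception as exc:
                raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
        runtimes[stage] = round(time.perf_counter() - t0, 3)
        manifest["stages"][stage] = {
            "inputs": sorted(state.get("_artifacts", {}).keys()),
            "outputs": {str(p.relative_to(outdir)): sha256_file(p) for p in outputs},
            "params": params,
            "param_hash": _params_hash(params),
            "seed": config.seed,
            "warnings": sorted({str(w.message) for w in caught}),
        }
        arts = state.setdefault("_artifacts", {})
        for p in outputs:
            arts[str(p.relative_to(outdir))] = stage
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(outdir / "runlog.json", "w") as fh:
        json.dump(runtimes, fh, indent=1, sort_keys=True)
    return manifest


# --------------------------------------------------------------------------
# Stages


def _stage_simulate(config: PipelineConfig, state: dict, outdir: Path):
    sc = config.synth_config()
    comp = synthdata.generate_compendium(sc)
    catalog = synthdata.generate_gwas_catalog(sc, comp.truth)
    if sc.n_swapped_tracks:
        comp.observed, registry = synthdata.plant_swaps(
            comp.observed, sc.n_swapped_tracks, sc.seed, kind="sample",
            sample_groups=comp.truth.sample_groups)
        comp.truth.swapped_pairs = registry
    written = synthdata.write_compendium(comp, outdir / "compendium", catalog)
    state.update(comp=comp, catalog=catalog)
    return written, {"synth": dataclasses.asdict(sc)}


def _stage_qc(config: PipelineConfig, state: dict, outdir: Path):
    comp = state["comp"]
    rows = []
    for key in sorted(comp.observed):
        m = trackqc.qc_metrics(comp.observed[key], comp.imputed[key])
        rows.append((f"{key[0]}:{key[1]}", m.genomewide_correlation,
                     m.peak_recovery_obs, m.peak_recovery_imp, m.auc))
    metrics = pd.DataFrame(rows, columns=["track_id", "correlation", "peak_recovery_obs",
                                          "peak_recovery_imp", "auc"])
    low = trackqc.flag_low_quality(dict(zip(metrics["track_id"], metrics["correlation"])))
    swaps = trackqc.detect_sample_swaps(comp.observed, comp.imputed)
    anti = trackqc.detect_antibody_swaps(comp.observed, comp.imputed)
    flags = pd.concat([
        pd.DataFrame({"track_id": low, "kind": "low_quality", "score_sd": np.nan,
                      "statistic": "elbow", "details": ""}),
        swaps, anti,
    ], ignore_index=True)
    p1, p2 = outdir / "qc_metrics.tsv", outdir / "qc_flags.tsv"
    write_tsv(metrics, p1)
    write_tsv(flags, p2)
    state.update(qc_metrics=metrics, qc_flags=flags)
    return [p1, p2], {"n_sd": 3.0, "top_k": 10}


def _stage_enhancers(config: PipelineConfig, state: dict, outdir: Path):
    comp = state["comp"]
    k27 = {s: comp.observed[(s, "H3K27ac")] for s in comp.metadata["sample"]}
    activity = enh_mod.call_active_enhancers(
        comp.dhs, comp.segmentations, k27,
        signal_threshold=config.signal_threshold, flank_bp=config.flank_bp)
    promoters = enh_mod.call_active_elements(
        comp.dhs, comp.segmentations, k27, states=enh_mod.PROMOTER_STATES,
        signal_threshold=config.signal_threshold, flank_bp=config.flank_bp,
        drop_inactive=False)
    enh_occ = pd.Series(activity.A.sum(axis=1), index=activity.elements["name"])
    prom_all = pd.Series(promoters.A.sum(axis=1), index=promoters.elements["name"])
    both = enh_occ.index.union(prom_all[prom_all > 0].index)
    e = enh_occ.reindex(both, fill_value=0)
    p = prom_all.reindex(both, fill_value=0)
    classes = enh_mod.classify_elements(e, p)
    p1 = outdir / "activity_matrix.tsv"
    p2 = outdir / "enhancers.bed"
    p3 = outdir / "element_classes.tsv"
    write_tsv(activity.to_frame(), p1, index=True)
    activity.elements.to_csv(p2, sep="\t", header=False, index=False)
    write_tsv(classes.rename_axis("element").reset_index(), p3)
    state.update(activity=activity, element_classes=classes)
    return [p1, p2, p3], {"signal_threshold": config.signal_threshold,
                          "flank_bp": config.flank_bp}


def _stage_modules(config: PipelineConfig, state: dict, outdir: Path):
    activity = state["activity"]
    if config.k_modules > len(np.unique(activity.A, axis=0)):
        raise ValueError(f"k={config.k_modules} exceeds the number of distinct activity rows")
    modules = enh_mod.cluster_modules(activity, k=config.k_modules, seed=config.seed)
    order = enh_mod.diagonalize(modules.centers.T)
    enrich = enh_mod.metadata_enrichment(modules, state["comp"].metadata)
    p1, p2, p3 = (outdir / "module_assignment.tsv", outdir / "module_centers.tsv",
                  outdir / "module_metadata_enrichment.tsv")
    write_tsv(modules.assignment.rename_axis("element").reset_index(), p1)
    write_tsv(modules.centers.loc[order], p2, index=True)
    write_tsv(enrich, p3)
    state.update(modules=modules)
    return [p1, p2, p3], {"k": config.k_modules, "seed": config.seed}


def _stage_link(config: PipelineConfig, state: dict, outdir: Path):
    comp, activity = state["comp"], state["activity"]
    marks = [m for m in ("H3K27ac", "H3K4me1") if m in comp.config.marks]
    signal = {}
    for m in marks:
        tracks = {s: comp.observed[(s, m)] for s in comp.metadata["sample"]}
        am = enh_mod.call_active_elements(comp.dhs, comp.segmentations, tracks,
                                          drop_inactive=False)
        signal[m] = am.signal_frame().loc[activity.elements["name"]]
    enh_bed = activity.elements.rename(columns={"name": "id"})
    cands = link_mod.candidate_correlations(comp.expression, signal, comp.tss, enh_bed)
    true_pairs = {(e, g) for e, g, _ in comp.truth.true_links}
    is_pos = [(e, g) in true_pairs for e, g in zip(cands["enhancer"], cands["gene"])]
    positives = cands[np.array(is_pos)]
    if positives.empty:
        raise ValueError("no true links among candidates; cannot train")
    negatives = link_mod.make_negatives(positives, comp.expression, signal,
                                        comp.tss, seed=config.seed)
    clf, feats = link_mod.train_link_classifier(positives, negatives, seed=config.seed)
    states = comp.truth.enhancers.set_index("id")["state"]
    links = link_mod.predict_links(clf, feats, cands, activity, states,
                                   threshold=config.link_threshold)
    p1 = outdir / "links.tsv"
    write_tsv(links, p1)
    state.update(links=links, link_candidates=cands)
    return [p1], {"threshold": config.link_threshold, "marks": marks, "seed": config.seed}


def _stage_gwas(config: PipelineConfig, state: dict, outdir: Path):
    comp, activity = state["comp"], state["activity"]
    pruned = gwas_mod.prune_catalog(state["catalog"], window_bp=config.prune_window_bp)
    enh_bed = activity.elements.rename(columns={"name": "id"})
    names = activity.elements["name"].to_numpy()
    sets = {s: set(names[activity.A[:, i]]) for i, s in enumerate(activity.samples)}
    flat = gwas_mod.flat_enrichment(pruned, sets, enh_bed,
                                    radius_bp=config.overlap_radius_bp, alpha=config.alpha)
    fdr, n_real, _ = gwas_mod.empirical_fdr(
        pruned, sets, enh_bed, n_shuffles=config.n_shuffles, seed=config.seed,
        radius_bp=config.overlap_radius_bp, alpha=config.alpha)
    tree = gwas_mod.build_tree(activity)
    tree_table = gwas_mod.tree_enrichment(pruned, tree, enh_bed,
                                          radius_bp=config.overlap_radius_bp,
                                          alpha=config.alpha)
    curve = gwas_mod.rarefaction_curve(flat)
    p1, p2, p3, p4, p5 = (outdir / "pruned_catalog.tsv", outdir / "flat_enrichment.tsv",
                          outdir / "tree_enrichment.tsv", outdir / "tree.nwk",
                          outdir / "rarefaction.tsv")
    write_tsv(pruned, p1)
    write_tsv(flat, p2)
    write_tsv(tree_table.sort_values(["node", "trait"], kind="stable",
                                     na_position="last"), p3)
    p4.write_text(tree.to_newick() + "\n")
    write_tsv(pd.DataFrame([(s, ";".join(ts)) for s, ts in curve],
                           columns=["set", "newly_covered"]), p5)
    fdr_path = outdir / "empirical_fdr.json"
    with open(fdr_path, "w") as fh:
        json.dump({"fdr": None if np.isnan(fdr) else fdr, "n_significant": n_real}, fh,
                  indent=1, sort_keys=True)
    state.update(pruned=pruned, flat=flat, tree=tree, tree_table=tree_table)
    return [p1, p2, p3, p4, p5, fdr_path], {
        "prune_window_bp": config.prune_window_bp, "radius_bp": config.overlap_radius_bp,
        "n_shuffles": config.n_shuffles, "alpha": config.alpha, "seed": config.seed}


def _stage_traits(config: PipelineConfig, state: dict, outdir: Path):
    comp, tree, tree_table = state["comp"], state["tree"], state["tree_table"]
    labels = traits_mod.assign_node_tissues(tree, comp.metadata)
    done = tree_table[tree_table["skipped"] == False]  # noqa: E712
    ttm = traits_mod.tissue_trait_matrix(done, labels)
    binary = (ttm > 0).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        classes = traits_mod.classify_traits(binary)
    sim = traits_mod.tissue_similarity(binary)
    genet = traits_mod.genetic_overlap_network(state["pruned"])
    p1, p2, p3, p4 = (outdir / "tissue_trait_matrix.tsv", outdir / "trait_classes.tsv",
                      outdir / "tissue_similarity.tsv", outdir / "genetic_network.tsv")
    write_tsv(ttm, p1, index=True)
    write_tsv(classes, p2)
    write_tsv(sim, p3, index=True)
    write_tsv(genet, p4)
    outputs = [p1, p2, p3, p4]
    norm = traits_mod.tissue_trait_matrix(done, labels, normalize=True)
    if (norm.sum(axis=0) > 0).sum() >= 2:
        G = traits_mod.trait_network(norm, edge_threshold=config.edge_threshold,
                                     layout_seed=config.seed)
        edges = pd.DataFrame(
            [(a, b, d["cosine_distance"], d["tissue"]) for a, b, d in G.edges(data=True)],
            columns=["trait_a", "trait_b", "cosine_distance", "tissue"])
        p5 = outdir / "trait_network.tsv"
        write_tsv(edges.sort_values(["trait_a", "trait_b"]), p5)
        outputs.append(p5)
    state.update(ttm=ttm, node_labels=labels)
    return outputs, {"edge_threshold": config.edge_threshold}


# --------------------------------------------------------------------------
# Locus reports


def locus_report(trait: str, lead_snp: tuple[str, int], tree_table: pd.DataFrame,
                 tree, links: pd.DataFrame, enhancers: pd.DataFrame,
                 sample_groups: pd.Series, selected_groups: list[str] | None = None,
                 radius_bp: int = 2_500, top_n: int = 3) -> dict:
    """Per-locus summary for one trait and lead SNP.

    Reports, for each of the ``top_n`` most enriched tree nodes of the
    trait, the nearest active enhancer within ``radius_bp`` of the SNP
    (explicitly stating absence), the genes linked from SNP-proximal
    enhancers in those nodes, and any link in the locus present in at
    least half of the samples of each selected tissue group.
    """
    sub = tree_table[(tree_table["trait"] == trait) & (tree_table["skipped"] == False)]  # noqa: E712
    if sub.empty:
        raise ValueError(f"trait {trait} absent from the enrichment table")
    top_nodes = sub.sort_values(["p_hyper", "node"], kind="stable")["node"].head(top_n)
    chrom, pos = lead_snp
    eid = enhancers["id"] if "id" in enhancers else enhancers["name"]
    mid1 = (enhancers["start"].to_numpy() + enhancers["end"].to_numpy()) // 2 + 1
    report = {"trait": trait, "lead_snp": f"{chrom}:{pos}", "nodes": []}
    proximal: set = set()
    element_ids = np.array(tree.element_ids)
    for node in top_nodes:
        mask = tree.nodes[int(node)].tested
        node_ids = set(element_ids[mask])
        cand = [(abs(int(pos) - int(m)), e) for e, m, c in zip(eid, mid1, enhancers["chrom"])
                if c == chrom and e in node_ids and abs(int(pos) - int(m)) <= radius_bp]
        entry = {"node": int(node), "nearest_enhancer": None,
                 "note": "no enhancer within 2.5 kb"}
        if cand:
            d, e = min(cand)
            entry = {"node": int(node), "nearest_enhancer": e, "distance_bp": d, "note": ""}
            proximal.add(e)
        report["nodes"].append(entry)
    direct = links[links["enhancer"].isin(proximal) & links["kept"]]
    report["direct_genes"] = sorted(direct["gene"].unique())
    group_links = []
    for g in selected_groups or []:
        members = set(sample_groups[sample_groups == g].index)
        in_locus = links[(links["kept"]) &
                         (links["enhancer"].map(dict(zip(eid, enhancers["chrom"]))) == chrom)]
        for (e, gene), subl in in_locus.groupby(["enhancer", "gene"]):
            frac = len(set(subl["biosample"]) & members) / max(1, len(members))
            if frac >= 0.5:
                group_links.append({"group": g, "enhancer": e, "gene": gene,
                                    "fraction": round(frac, 3)})
    report["group_links"] = group_links
    return report
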