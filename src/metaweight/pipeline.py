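"""End-to-end orchestration: sample -> weight -> correlate -> classify ->
pathway report -> compression sweep -> shared-part analysis.

All stages are driven by one :class:`RunConfig`; every stochastic stage takes
its stream from the single master seed, so two runs with identical config and
inputs produce byte-identical report files (verified by the manifest's
per-file checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__, io
from .compression import (WeightedGraph, compress_sweep, compress_to_ratio,
                          compressed_weight_profile, pathway_similarity,
                          rank_pathways, shared_compressed_part)
from .graph import build_pathway_graph, build_supergraph
from .sampling import sample_datasets
from .stats import (ClassificationConfig, classify_enzymes, paired_inter_weights,
                    pathway_ratios, permutation_test, spearman)
from .weighting import (aggregate_weights, isoenzymatic_weights,
                        seqsim_weights, taxonomic_weights)

log = logging.getLogger("metaweight")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    seed: int
    reactions: str
    cofactors: str
    pathways: str
    profiles: str
    fasta: str | None
    clusters: str
    k: int = 15
    replicates: int = 100
    m: int = 1000
    t_high: float = 0.667
    iso_t_high: float = 1.0
    iso_t_low: float = 1.0
    min_weighted: int = 10
    target_crs: Sequence[float] = (0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)
    kinds: Sequence[str] = ("taxonomic", "isoenzymatic", "seqsim")
    seqsim_replicates: int | None = None  # cap alignment-heavy replicates

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self) -> None:
        for name in ("reactions", "cofactors", "pathways", "profiles",
                     "clusters"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if "seqsim" in self.kinds:
            if self.fasta is None or not Path(self.fasta).exists():
                raise FileNotFoundError(
                    "seqsim weights requested but no FASTA of protein "
                    "sequences is available")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _cfg_for_kind(cfg: RunConfig, kind: str) -> ClassificationConfig:
    if kind == "isoenzymatic":
        return ClassificationConfig(t_high=cfg.iso_t_high, t_low=cfg.iso_t_low)
    return ClassificationConfig(t_high=cfg.t_high)


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full study design; returns the report directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage: %s", name)

    stage("read inputs")
    reactions = io.read_reactions(config.reactions)
    cofactors = io.read_cofactors(config.cofactors)
    membership, names = io.read_pathways(config.pathways)
    sequences = io.read_fasta(config.fasta) if config.fasta else {}
    profiles = io.read_profiles(config.profiles, sequences=sequences)
    clusters = io.read_clusters(config.clusters)

    stage("build graph")
    sg = build_supergraph(reactions, cofactors, pathway_membership=membership)
    pathway_graphs = {
        pid: build_pathway_graph(sg, pid, reactions, cofactors)
        for pid in sorted(membership)
    }

    stage("sample")
    datasets = sample_datasets(clusters, k=config.k,
                               replicates=config.replicates, seed=config.seed)
    io.write_datasets(datasets, outdir / "datasets.tsv")
    domains = sorted({d.domain for d in datasets})
    if len(domains) != 2:
        raise ValueError(f"expected exactly 2 domains, found {domains}")

    stage("weight")
    vectors: dict[tuple[str, str], list] = {}
    for kind in config.kinds:
        cap = (config.seqsim_replicates
               if kind == "seqsim" and config.seqsim_replicates is not None
               else config.replicates)
        for ds in datasets:
            if ds.replicate_index >= cap:
                continue
            if kind == "taxonomic":
                vec = taxonomic_weights(ds, profiles, sg)
            elif kind == "isoenzymatic":
                vec = isoenzymatic_weights(ds, profiles, sg)
            else:
                vec = seqsim_weights(ds, profiles, sg, seed=config.seed)
            vectors.setdefault((kind, ds.domain), []).append(vec)
    for (kind, domain), vecs in sorted(vectors.items()):
        io.write_weights(vecs, outdir / f"weights_{kind}_{domain}.tsv",
                         enzymes=sg.nodes)
    agg = {key: aggregate_weights(vecs) for key, vecs in vectors.items()}

    stage("correlate")
    rows = []
    # intra-domain correlations between weight kinds, per replicate, averaged
    kind_pairs = [(a, b) for i, a in enumerate(config.kinds)
                  for b in config.kinds[i + 1:]]
    for domain in domains:
        for ka, kb in kind_pairs:
            va = {v.dataset_id: v for v in vectors.get((ka, domain), [])}
            vb = {v.dataset_id: v for v in vectors.get((kb, domain), [])}
            rhos, ps, pps = [], [], []
            for did in sorted(set(va) & set(vb)):
                common = sorted(set(va[did].values) & set(vb[did].values))
                x = [va[did].values[ec] for ec in common]
                y = [vb[did].values[ec] for ec in common]
                try:
                    res = spearman(x, y)
                except ValueError:
                    continue
                tailp = permutation_test(
                    x, y, m=config.m, seed=config.seed,
                    tail="greater" if res.rho >= 0 else "less")
                rhos.append(res.rho)
                ps.append(res.p_analytic)
                pps.append(tailp)
            if rhos:
                rows.append({
                    "kind_pair": f"{ka}~{kb}", "domain": domain,
                    "rho_mean": sum(rhos) / len(rhos),
                    "p_mean": sum(ps) / len(ps),
                    "permutation_p_mean": sum(pps) / len(pps)})
    # inter-domain correlation per kind on aggregated mean weights
    for kind in config.kinds:
        key_a, key_b = (kind, domains[0]), (kind, domains[1])
        if key_a not in agg or key_b not in agg:
            continue
        _, xa, xb = paired_inter_weights(agg[key_a], agg[key_b])
        res = spearman(xa, xb)
        tailp = permutation_test(xa, xb, m=config.m, seed=config.seed,
                                 tail="greater" if res.rho >= 0 else "less")
        rows.append({"kind_pair": kind, "domain": "inter",
                     "rho_mean": res.rho, "p_mean": res.p_analytic,
                     "permutation_p_mean": tailp})
    pd.DataFrame(rows, columns=["kind_pair", "domain", "rho_mean", "p_mean",
                                "permutation_p_mean"]).to_csv(
        outdir / "correlations.tsv", sep="\t", index=False,
        float_format="%.10g")

    stage("classify")
    class_rows = []
    classes_by_kind = {}
    for kind in config.kinds:
        key_a, key_b = (kind, domains[0]), (kind, domains[1])
        if key_a not in agg or key_b not in agg:
            continue
        classes = classify_enzymes(agg[key_a], agg[key_b],
                                   _cfg_for_kind(config, kind))
        classes_by_kind[kind] = classes
        class_rows.extend({"ec": c.ec, "kind": kind, "label": c.label}
                          for c in classes)
    pd.DataFrame(class_rows, columns=["ec", "kind", "label"]).sort_values(
        ["kind", "ec"]).to_csv(outdir / "classes.tsv", sep="\t", index=False)

    stage("pathway report")
    if "taxonomic" in classes_by_kind:
        ratios = pathway_ratios(
            list(pathway_graphs.values()), classes_by_kind["taxonomic"],
            agg[("taxonomic", domains[0])], agg[("taxonomic", domains[1])],
            min_weighted=config.min_weighted)
        ratios.to_csv(outdir / "pathway_ratios.tsv", sep="\t", index=False,
                      float_format="%.10g")

    stage("compress")
    comp_rows = []
    if ("taxonomic", domains[0]) in agg:
        results = {}
        graphs = {}
        for domain in domains:
            weights = agg[("taxonomic", domain)].mean_values
            graphs[domain] = WeightedGraph.from_supergraph(sg, weights)
            sweep = compress_sweep(graphs[domain], config.target_crs)
            for cr, res in sweep.items():
                results[(domain, cr)] = res
        for cr in config.target_crs:
            ra, rb = results[(domains[0], cr)], results[(domains[1], cr)]
            for domain, res in ((domains[0], ra), (domains[1], rb)):
                other = rb if domain == domains[0] else ra
                shared = shared_compressed_part(
                    res, other, graphs[domain].node_weight)
                comp_rows.append({
                    "domain": domain, "target_cr": cr,
                    "achieved_cr": res.cr, "distance": res.distance,
                    "distance_bound": res.distance_bound,
                    "mean_weight_retained":
                        compressed_weight_profile(res, graphs[domain]),
                    "mean_weight_shared":
                        "NA" if shared is None else shared})
        pd.DataFrame(comp_rows).to_csv(outdir / "compression.tsv", sep="\t",
                                       index=False, float_format="%.10g")

        # per-pathway compression at the deepest ratio
        deepest = min(config.target_crs)
        sims = {}
        for domain in domains:
            weights = agg[("taxonomic", domain)].mean_values
            per = {}
            for pid, pw in pathway_graphs.items():
                pgraph = WeightedGraph(
                    node_weight={v: float(weights.get(v, 0.0))
                                 for v in pw.enzymes},
                    edge_weight={tuple(sorted(e)): 1.0 for e in pw.edges})
                if pgraph.size == 0:
                    continue
                res = compress_to_ratio(pgraph, deepest)
                per[pid] = pathway_similarity(pgraph, res, pathway_id=pid)
            sims[domain] = per
        try:
            table, rho = rank_pathways(sims[domains[0]], sims[domains[1]],
                                       names=names)
            table.to_csv(outdir / "pathway_similarity.tsv", sep="\t",
                         index=False, float_format="%.10g")
            (outdir / "pathway_rank_correlation.json").write_text(
                json.dumps({"spearman_rho": rho}, indent=1))
        except ValueError:
            log.warning("too few common pathways for ranking")

    stage("manifest")
    outputs = sorted(p for p in outdir.iterdir() if p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "checksums": {p.name: _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return outdir
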