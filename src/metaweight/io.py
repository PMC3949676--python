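"""Readers and writers for the tabular interchange formats.

All tables are TSV with a header row.  Missing values are serialized as
"NA"; zero and NA are never conflated.  Parse errors report 1-based file
line numbers.  Outputs are sorted before writing so reruns are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .graph import Pathway, Reaction, SuperGraph
from .sampling import ClusterAssignment, SampledDataset
from .weighting import GenomeProfile, WeightVector

__all__ = [
    "read_reactions", "write_reactions",
    "read_cofactors", "write_cofactors",
    "read_pathways", "write_pathways",
    "read_clusters", "write_clusters",
    "read_profiles", "write_profiles",
    "read_fasta", "write_fasta",
    "read_datasets", "write_datasets",
    "read_weights", "write_weights",
    "write_graph_tsv", "write_graphml",
]


class ParseError(ValueError):
    pass


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return df


def _split(cell: str) -> frozenset[str]:
    return frozenset(x for x in cell.split(";") if x)


def read_reactions(path: str | Path) -> list[Reaction]:
    df = _read_tsv(path, ["reaction_id", "ec_numbers", "substrates", "products"])
    has_pw = "pathways" in df.columns
    out, seen = [], set()
    for idx, row in df.iterrows():
        line = idx + 2
        rid = row["reaction_id"]
        if rid in seen:
            raise ParseError(f"{path}:{line}: duplicate reaction_id {rid!r}")
        seen.add(rid)
        ecs = _split(row["ec_numbers"])
        if not ecs:
            raise ParseError(f"{path}:{line}: reaction {rid!r} has no EC numbers")
        out.append(Reaction(
            reaction_id=rid, ec_numbers=ecs,
            substrates=_split(row["substrates"]),
            products=_split(row["products"]),
            pathways=_split(row["pathways"]) if has_pw else frozenset()))
    return out


def write_reactions(reactions: Iterable[Reaction], path: str | Path) -> None:
    rows = [{
        "reaction_id": r.reaction_id,
        "ec_numbers": ";".join(sorted(r.ec_numbers)),
        "substrates": ";".join(sorted(r.substrates)),
        "products": ";".join(sorted(r.products)),
        "pathways": ";".join(sorted(r.pathways)),
    } for r in sorted(reactions, key=lambda r: r.reaction_id)]
    pd.DataFrame(rows, columns=["reaction_id", "ec_numbers", "substrates",
                                "products", "pathways"]).to_csv(
        path, sep="\t", index=False)


def read_cofactors(path: str | Path) -> set[str]:
    out = set()
    for raw in Path(path).read_text().splitlines():
        entry = raw.split("#", 1)[0].strip()
        if entry:
            out.add(entry)
    return out


def write_cofactors(cofactors: Iterable[str], path: str | Path) -> None:
    Path(path).write_text(
        "# cofactor exclusion list\n" +
        "".join(f"{c}\n" for c in sorted(cofactors)))


def read_pathways(path: str | Path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Returns (pathway_id -> EC set, pathway_id -> name)."""
    df = _read_tsv(path, ["pathway_id", "name", "ec"])
    membership: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for idx, row in df.iterrows():
        pid = row["pathway_id"]
        membership.setdefault(pid, set()).add(row["ec"])
        prev = names.setdefault(pid, row["name"])
        if prev != row["name"]:
            raise ParseError(
                f"{path}:{idx + 2}: pathway {pid!r} has conflicting names")
    return membership, names


def write_pathways(membership: Mapping[str, Iterable[str]],
                   names: Mapping[str, str], path: str | Path) -> None:
    rows = [{"pathway_id": p, "name": names.get(p, p), "ec": ec}
            for p in sorted(membership) for ec in sorted(membership[p])]
    pd.DataFrame(rows, columns=["pathway_id", "name", "ec"]).to_csv(
        path, sep="\t", index=False)


def read_clusters(path: str | Path) -> list[ClusterAssignment]:
    df = _read_tsv(path, ["genome_id", "domain", "cluster_id"])
    out, seen = [], set()
    for idx, row in df.iterrows():
        if row["genome_id"] in seen:
            raise ParseError(
                f"{path}:{idx + 2}: duplicate genome_id {row['genome_id']!r}")
        seen.add(row["genome_id"])
        out.append(ClusterAssignment(row["genome_id"], row["domain"],
                                     row["cluster_id"]))
    return out


def write_clusters(assignments: Iterable[ClusterAssignment],
                   path: str | Path) -> None:
    rows = [{"genome_id": a.genome_id, "domain": a.domain,
             "cluster_id": a.cluster_id}
            for a in sorted(assignments, key=lambda a: a.genome_id)]
    pd.DataFrame(rows, columns=["genome_id", "domain", "cluster_id"]).to_csv(
        path, sep="\t", index=False)


def read_profiles(path: str | Path,
                  sequences: Mapping[str, str] | None = None,
                  ) -> dict[str, GenomeProfile]:
    """Parse genome profile rows (genome_id, domain, ec, protein_id).

    Duplicate (genome, ec, protein) rows and genomes spanning domains are
    rejected with line numbers.  ``sequences`` (e.g. from ``read_fasta``) is
    attached to every profile when given.
    """
    df = _read_tsv(path, ["genome_id", "domain", "ec", "protein_id"])
    enz: dict[str, dict[str, list[str]]] = {}
    domains: dict[str, str] = {}
    seen: set[tuple[str, str, str]] = set()
    for idx, row in df.iterrows():
        line = idx + 2
        g, d, ec, pid = (row["genome_id"], row["domain"], row["ec"],
                         row["protein_id"])
        key = (g, ec, pid)
        if key in seen:
            raise ParseError(f"{path}:{line}: duplicate row {key!r}")
        seen.add(key)
        prev = domains.setdefault(g, d)
        if prev != d:
            raise ParseError(
                f"{path}:{line}: genome {g!r} listed under two domains")
        enz.setdefault(g, {}).setdefault(ec, []).append(pid)
    seqs = sequences if sequences is not None else {}
    return {
        g: GenomeProfile(genome_id=g, domain=domains[g],
                         enzymes={ec: tuple(sorted(p)) for ec, p in e.items()},
                         sequences=seqs)
        for g, e in enz.items()
    }


def write_profiles(profiles: Mapping[str, GenomeProfile],
                   path: str | Path) -> None:
    rows = [{"genome_id": g, "domain": p.domain, "ec": ec, "protein_id": pid}
            for g, p in sorted(profiles.items())
            for ec in sorted(p.enzymes)
            for pid in sorted(p.enzymes[ec])]
    pd.DataFrame(rows, columns=["genome_id", "domain", "ec", "protein_id"]
                 ).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sorted(sequences.items())]
    SeqIO.write(records, str(path), "fasta")


def read_datasets(path: str | Path) -> list[SampledDataset]:
    df = _read_tsv(path, ["dataset_id", "domain", "replicate_index",
                          "genome_id"])
    grouped: dict[str, dict] = {}
    for _, row in df.iterrows():
        g = grouped.setdefault(row["dataset_id"], {
            "domain": row["domain"],
            "replicate_index": int(row["replicate_index"]),
            "genomes": []})
        g["genomes"].append(row["genome_id"])
    return [SampledDataset(dataset_id=did, domain=g["domain"],
                           genome_ids=tuple(g["genomes"]),
                           replicate_index=g["replicate_index"])
            for did, g in grouped.items()]


def write_datasets(datasets: Iterable[SampledDataset],
                   path: str | Path) -> None:
    rows = [{"dataset_id": d.dataset_id, "domain": d.domain,
             "replicate_index": d.replicate_index, "genome_id": g}
            for d in sorted(datasets, key=lambda d: d.dataset_id)
            for g in d.genome_ids]
    pd.DataFrame(rows, columns=["dataset_id", "domain", "replicate_index",
                                "genome_id"]).to_csv(path, sep="\t",
                                                     index=False)


def read_weights(path: str | Path) -> list[WeightVector]:
    df = _read_tsv(path, ["dataset_id", "domain", "kind", "ec", "weight"])
    vectors: dict[tuple[str, str], WeightVector] = {}
    for _, row in df.iterrows():
        key = (row["dataset_id"], row["kind"])
        vec = vectors.setdefault(key, WeightVector(
            kind=row["kind"], dataset_id=row["dataset_id"],
            domain=row["domain"], values={}))
        if row["weight"] != "NA":
            vec.values[row["ec"]] = float(row["weight"])
    return list(vectors.values())


def write_weights(vectors: Iterable[WeightVector], path: str | Path,
                  enzymes: Iterable[str] | None = None) -> None:
    """Serialize weight vectors; missing enzymes are written as NA rows when
    the full enzyme universe is supplied."""
    universe = sorted(enzymes) if enzymes is not None else None
    rows = []
    for vec in sorted(vectors, key=lambda v: (v.kind, v.dataset_id)):
        ecs = universe if universe is not None else sorted(vec.values)
        for ec in ecs:
            w = vec.values.get(ec)
            rows.append({
                "dataset_id": vec.dataset_id, "domain": vec.domain,
                "kind": vec.kind, "ec": ec,
                "weight": "NA" if w is None else repr(float(w))})
    pd.DataFrame(rows, columns=["dataset_id", "domain", "kind", "ec",
                                "weight"]).to_csv(path, sep="\t", index=False)


def write_graph_tsv(graph: SuperGraph | Pathway, prefix: str | Path,
                    weights: Mapping[str, Mapping[str, float]] | None = None,
                    ) -> tuple[Path, Path]:
    """Two-file TSV export: <prefix>.nodes.tsv and <prefix>.edges.tsv.

    ``weights`` maps column name -> (EC -> weight); missing entries are NA.
    """
    prefix = Path(prefix)
    nodes = sorted(graph.nodes if isinstance(graph, SuperGraph)
                   else graph.enzymes)
    cols = dict(weights or {})
    rows = []
    for ec in nodes:
        row = {"ec": ec}
        for name, mapping in cols.items():
            w = mapping.get(ec)
            row[name] = "NA" if w is None else repr(float(w))
        rows.append(row)
    nodes_path = prefix.with_suffix(".nodes.tsv")
    edges_path = prefix.with_suffix(".edges.tsv")
    pd.DataFrame(rows, columns=["ec", *cols]).to_csv(nodes_path, sep="\t",
                                                     index=False)
    erows = [{"ec_a": a, "ec_b": b}
             for a, b in sorted(tuple(sorted(e)) for e in graph.edges)]
    pd.DataFrame(erows, columns=["ec_a", "ec_b"]).to_csv(edges_path, sep="\t",
                                                         index=False)
    return nodes_path, edges_path


def write_graphml(graph: SuperGraph, path: str | Path,
                  weights: Mapping[str, Mapping[str, float]] | None = None,
                  ) -> None:
    g = graph.to_networkx()
    for name, mapping in (weights or {}).items():
        nx.set_node_attributes(
            g, {ec: float(w) for ec, w in mapping.items() if ec in g}, name)
    nx.write_graphml(g, str(path))


def write_truth(truth, path: str | Path) -> None:
    payload = {
        "planted_specific": {d: sorted(s)
                             for d, s in truth.planted_specific.items()},
        "planted_ubiquitous": sorted(truth.planted_ubiquitous),
        "planted_core": sorted(truth.planted_core),
        "true_probs": {d: dict(sorted(p.items()))
                       for d, p in truth.true_probs.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_scenario(scenario, outdir: str | Path) -> dict[str, Path]:
    """Emit a synthetic scenario as the full set of interchange files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g, d = scenario.graph, scenario.domains
    paths = {
        "reactions": outdir / "reactions.tsv",
        "cofactors": outdir / "cofactors.txt",
        "pathways": outdir / "pathways.tsv",
        "profiles": outdir / "profiles.tsv",
        "proteins": outdir / "proteins.faa",
        "rrna": outdir / "rrna.fasta",
        "clusters": outdir / "clusters.tsv",
        "truth": outdir / "truth.json",
    }
    write_reactions(g.reactions, paths["reactions"])
    write_cofactors(g.cofactors, paths["cofactors"])
    write_pathways(g.pathway_membership, g.pathway_names, paths["pathways"])
    write_profiles(d.profiles, paths["profiles"])
    write_fasta(d.sequences, paths["proteins"])
    write_fasta(d.rrna, paths["rrna"])
    write_clusters(d.clusters, paths["clusters"])
    write_truth(d.truth, paths["truth"])
    return paths
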