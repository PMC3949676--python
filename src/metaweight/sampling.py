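"""Stratified genome sampling across evolutionary space.

Genomes are first clustered on 16S rRNA similarity (clusterings are consumed
as input; an internal greedy clusterer exists so synthetic pipelines are
self-contained).  A sampled dataset draws at most one genome per cluster so
that over-sequenced clades (pathogens, lab strains) cannot dominate: when a
domain has exactly ``k`` clusters every cluster contributes one genome, and
when it has more, ``k`` clusters are first drawn uniformly without
replacement.  Repeating the draw ``replicates`` times per domain yields the
paired-domain dataset collection the downstream weights are averaged over.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ClusterAssignment",
    "SampledDataset",
    "InsufficientDiversityError",
    "sample_datasets",
    "naive_cluster",
]


@dataclass(frozen=True)
class ClusterAssignment:
    genome_id: str
    domain: str
    cluster_id: str


@dataclass(frozen=True)
class SampledDataset:
    """One domain-stratified draw of genomes (one genome per chosen cluster)."""

    dataset_id: str
    domain: str
    genome_ids: tuple[str, ...]
    replicate_index: int


class InsufficientDiversityError(ValueError):
    """A domain has fewer clusters than the requested dataset size."""


def _validate(assignments: Sequence[ClusterAssignment]) -> None:
    seen: dict[str, ClusterAssignment] = {}
    cluster_domain: dict[str, str] = {}
    for a in assignments:
        if a.genome_id in seen:
            raise ValueError(f"genome {a.genome_id!r} assigned twice")
        seen[a.genome_id] = a
        prev = cluster_domain.setdefault(a.cluster_id, a.domain)
        if prev != a.domain:
            raise ValueError(f"cluster {a.cluster_id!r} spans domains")


def sample_datasets(
    assignments: Sequence[ClusterAssignment],
    k: int = 15,
    replicates: int = 100,
    seed: int = 0,
) -> list[SampledDataset]:
    """Draw ``replicates`` stratified datasets of ``k`` genomes per domain.

    Per replicate and domain: if the domain has exactly ``k`` clusters, all
    are used and only the within-cluster genome choice varies; with more than
    ``k`` clusters, ``k`` clusters are chosen uniformly without replacement
    first.  Fewer than ``k`` clusters raises
    :class:`InsufficientDiversityError`.

    Randomness is drawn from per-(domain, replicate) streams derived from the
    master seed, so adding replicates never changes earlier datasets.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    _validate(assignments)
    by_domain: dict[str, dict[str, list[str]]] = {}
    for a in assignments:
        by_domain.setdefault(a.domain, {}).setdefault(a.cluster_id, []).append(
            a.genome_id)
    out: list[SampledDataset] = []
    for d_idx, domain in enumerate(sorted(by_domain)):
        clusters = by_domain[domain]
        cluster_ids = sorted(clusters)
        if len(cluster_ids) < k:
            raise InsufficientDiversityError(
                f"domain {domain!r} has {len(cluster_ids)} clusters, need {k}")
        for rep in range(replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(d_idx, rep)))
            if len(cluster_ids) == k:
                chosen = list(cluster_ids)
            else:
                idx = rng.choice(len(cluster_ids), size=k, replace=False)
                chosen = [cluster_ids[i] for i in sorted(idx)]
            genomes = []
            for cid in chosen:
                members = sorted(clusters[cid])
                genomes.append(members[rng.integers(len(members))])
            out.append(SampledDataset(
                dataset_id=f"{domain}-r{rep:03d}", domain=domain,
                genome_ids=tuple(genomes), replicate_index=rep))
    return out


def _kmers(seq: str, k: int) -> set[str]:
    if len(seq) < k:
        return {seq}
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def kmer_identity(a: str, b: str, k: int = 8) -> float:
    """Shared-k-mer fraction, normalised by the larger k-mer set.

    1.0 for identical sequences; a cheap stand-in for alignment identity that
    is adequate for well-separated cluster structure.
    """
    ka, kb = _kmers(a, k), _kmers(b, k)
    return len(ka & kb) / max(len(ka), len(kb))


def naive_cluster(
    sequences: Mapping[str, str],
    identity_threshold: float,
    k: int = 8,
) -> dict[str, str]:
    """Greedy longest-first clustering of one sequence per genome.

    A sequence joins the first existing cluster whose *representative* (the
    founding, longest sequence) has k-mer identity >= the threshold, else it
    founds a new cluster.  Deterministic; returns genome id -> cluster id.
    Raises ``ValueError`` on empty input.
    """
    if not sequences:
        raise ValueError("nothing to cluster")
    order = sorted(sequences, key=lambda g: (-len(sequences[g]), g))
    reps: list[tuple[str, str]] = []  # (cluster_id, representative sequence)
    assignment: dict[str, str] = {}
    for gid in order:
        seq = sequences[gid]
        for cid, rep in reps:
            if kmer_identity(seq, rep, k=k) >= identity_threshold:
                assignment[gid] = cid
                break
        else:
            cid = f"K{len(reps):04d}"
            reps.append((cid, seq))
            assignment[gid] = cid
    return assignment
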