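"""Node weights summarising many genomes on one enzyme graph.

Three weight kinds are computed per sampled dataset:

* **taxonomic** -- the fraction of the dataset's genomes containing the
  enzyme; range [0, 1].  High means phylogenetically ubiquitous in the
  domain.
* **isoenzymatic** -- the mean number of distinct protein forms of the
  enzyme per *containing* genome; range [0, inf).  High means redundancy.
  (Enzymes absent from every genome get 0, so zero presence and zero
  redundancy agree with the taxonomic weight.)
* **seqsim** -- pick one representative protein per containing genome
  (seeded choice keyed on genome id), align all unordered pairs, and take
  the mean similarity; range [0, 1].  High means sequence conservation.
  Undefined (missing) for enzymes in fewer than two genomes.

Weights of one kind and domain are aggregated across replicate datasets by
the per-enzyme mean over replicates where the value is defined, with the
support (number of defining replicates) recorded.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .align import pairwise_similarity
from .graph import SuperGraph
from .sampling import SampledDataset

__all__ = [
    "GenomeProfile",
    "WeightVector",
    "AggregatedWeights",
    "taxonomic_weights",
    "isoenzymatic_weights",
    "seqsim_weights",
    "aggregate_weights",
]

KINDS = ("taxonomic", "isoenzymatic", "seqsim")


@dataclass
class GenomeProfile:
    """One genome's enzyme content.

    ``enzymes`` maps EC -> non-empty tuple of protein ids; ``sequences``
    maps protein id -> amino-acid string (may be a shared mapping, and may
    be empty when only presence/counts are needed).
    """

    genome_id: str
    domain: str
    enzymes: dict[str, tuple[str, ...]]
    sequences: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for ec, pids in self.enzymes.items():
            if not pids:
                raise ValueError(
                    f"genome {self.genome_id!r}: empty protein list for {ec}")
            for p in pids:
                if p in seen:
                    raise ValueError(
                        f"genome {self.genome_id!r}: duplicate protein id {p!r}")
                seen.add(p)


@dataclass
class WeightVector:
    """One weight kind's values for one sampled dataset.

    ``values`` maps EC -> weight; an EC absent from the mapping is *missing*
    (undefined), which is distinct from a stored 0.0.
    """

    kind: str
    dataset_id: str
    domain: str
    values: dict[str, float]


@dataclass
class AggregatedWeights:
    """Per-enzyme mean weight across replicate datasets of one domain."""

    kind: str
    domain: str
    mean_values: dict[str, float]
    support: dict[str, int]
    n_replicates: int


def _profiles_for(
    dataset: SampledDataset,
    profiles: Mapping[str, GenomeProfile],
) -> list[GenomeProfile]:
    missing = [g for g in dataset.genome_ids if g not in profiles]
    if missing:
        raise KeyError(f"no profile for genome(s) {missing!r}")
    return [profiles[g] for g in dataset.genome_ids]


def taxonomic_weights(
    dataset: SampledDataset,
    profiles: Mapping[str, GenomeProfile],
    supergraph: SuperGraph,
) -> WeightVector:
    """Presence fraction per enzyme: (genomes containing v) / dataset size."""
    selected = _profiles_for(dataset, profiles)
    k = len(selected)
    values = {}
    for v in supergraph.nodes:
        values[v] = sum(1 for p in selected if v in p.enzymes) / k
    return WeightVector("taxonomic", dataset.dataset_id, dataset.domain, values)


def isoenzymatic_weights(
    dataset: SampledDataset,
    profiles: Mapping[str, GenomeProfile],
    supergraph: SuperGraph,
) -> WeightVector:
    """Mean distinct-protein count per containing genome (0 when absent)."""
    selected = _profiles_for(dataset, profiles)
    values = {}
    for v in supergraph.nodes:
        counts = [len(p.enzymes[v]) for p in selected if v in p.enzymes]
        values[v] = float(np.mean(counts)) if counts else 0.0
    return WeightVector("isoenzymatic", dataset.dataset_id, dataset.domain,
                        values)


def _stream(seed: int, *parts: str) -> np.random.Generator:
    # Stable per-(dataset, enzyme, genome) stream so representative choice is
    # independent of iteration order and genome position.
    key = tuple(zlib.crc32(p.encode()) for p in parts)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def choose_representative(
    seed: int,
    dataset_id: str,
    ec: str,
    genome: GenomeProfile,
) -> str:
    """Seeded uniform choice of one protein id of *ec* in *genome*."""
    pids = sorted(genome.enzymes[ec])
    rng = _stream(seed, dataset_id, ec, genome.genome_id)
    return pids[rng.integers(len(pids))]


def seqsim_weights(
    dataset: SampledDataset,
    profiles: Mapping[str, GenomeProfile],
    supergraph: SuperGraph,
    similarity: Callable[[str, str], float] = pairwise_similarity,
    seed: int = 0,
) -> WeightVector:
    """Mean pairwise similarity of one representative sequence per genome.

    Enzymes present in fewer than two of the dataset's genomes are missing
    (absent from the result's value mapping).  Raises ``KeyError`` when a
    chosen protein id has no sequence.
    """
    selected = _profiles_for(dataset, profiles)
    values: dict[str, float] = {}
    for v in sorted(supergraph.nodes):
        containing = [p for p in selected if v in p.enzymes]
        if len(containing) < 2:
            continue
        seqs = []
        for p in containing:
            pid = choose_representative(seed, dataset.dataset_id, v, p)
            if pid not in p.sequences:
                raise KeyError(
                    f"protein {pid!r} (genome {p.genome_id!r}) has no sequence")
            seqs.append(p.sequences[pid])
        sims = [similarity(seqs[i], seqs[j])
                for i in range(len(seqs)) for j in range(i + 1, len(seqs))]
        values[v] = float(np.mean(sims))
    return WeightVector("seqsim", dataset.dataset_id, dataset.domain, values)


def aggregate_weights(vectors: Sequence[WeightVector]) -> AggregatedWeights:
    """Per-enzyme mean over replicates where the value is defined."""
    if not vectors:
        raise ValueError("no weight vectors to aggregate")
    kinds = {v.kind for v in vectors}
    domains = {v.domain for v in vectors}
    if len(kinds) > 1 or len(domains) > 1:
        raise ValueError(
            f"inconsistent aggregation: kinds {kinds}, domains {domains}")
    sums: dict[str, float] = {}
    support: dict[str, int] = {}
    for vec in vectors:
        for ec, w in vec.values.items():
            sums[ec] = sums.get(ec, 0.0) + w
            support[ec] = support.get(ec, 0) + 1
    means = {ec: sums[ec] / support[ec] for ec in sums}
    return AggregatedWeights(kind=kinds.pop(), domain=domains.pop(),
                             mean_values=means, support=support,
                             n_replicates=len(vectors))
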