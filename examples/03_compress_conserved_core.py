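"""Compress node-weighted graphs and probe the shared conserved core.

Builds taxonomic-weighted graphs for two domains with a planted shared
high-occurrence core, sweeps the greedy compression from cr 0.8 down to 0.1,
and prints the mean weight of retained enzymes and of the part retained in
BOTH domains.  More compression removes low-weight periphery first, so both
series rise, and the shared part is enriched for the conserved core.
"""

from metaweight import (WeightedGraph, aggregate_weights, build_supergraph,
                        compressed_weight_profile, sample_datasets,
                        shared_compressed_part, taxonomic_weights)
from metaweight.compression import compress_sweep
from metaweight.synthetic import core_scenario

sc = core_scenario(seed=5)
sg = build_supergraph(sc.graph.reactions, sc.graph.cofactors)
datasets = sample_datasets(sc.domains.clusters, k=15, replicates=30, seed=6)

crs = (0.8, 0.6, 0.4, 0.2, 0.1)
graphs, sweeps = {}, {}
for dom in ("A", "B"):
    agg = aggregate_weights([taxonomic_weights(d, sc.domains.profiles, sg)
                             for d in datasets if d.domain == dom])
    graphs[dom] = WeightedGraph.from_supergraph(sg, agg.mean_values)
    sweeps[dom] = compress_sweep(graphs[dom], crs)

print(f"{'cr':>5s} {'mean weight (A)':>16s} {'shared-part mean':>17s} "
      f"{'distance bound':>15s}")
for cr in crs:
    res = sweeps["A"][cr]
    whole = compressed_weight_profile(res, graphs["A"])
    shared = shared_compressed_part(res, sweeps["B"][cr],
                                    graphs["A"].node_weight)
    print(f"{cr:>5.2f} {whole:>16.3f} {shared:>17.3f} "
          f"{res.distance_bound:>15.2f}")
print("\nAs cr shrinks the surviving enzymes are ever more ubiquitous, and")
print("the enzymes surviving in BOTH domains (the shared compressed part)")
print("are more ubiquitous still: the signature of a conserved core.")
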