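"""Compare two domains: correlations, permutation tests, enzyme classes.

Aggregates taxonomic weights over replicate sampled datasets in each domain,
correlates the mean weights across domains, attaches a permutation p-value
(weights shuffled over the fixed graph topology), and classifies enzymes as
domain-specific or ubiquitous at the 0.667 threshold, comparing the calls
against the planted ground truth.
"""

from collections import Counter

from metaweight import (ClassificationConfig, aggregate_weights,
                        build_supergraph, classify_enzymes, permutation_test,
                        sample_datasets, spearman, taxonomic_weights)
from metaweight.stats import paired_inter_weights
from metaweight.synthetic import standard_scenario

sc = standard_scenario(seed=3, seq_len_range=(60, 90))
sg = build_supergraph(sc.graph.reactions, sc.graph.cofactors)
datasets = sample_datasets(sc.domains.clusters, k=15, replicates=50, seed=4)

agg = {}
for dom in ("A", "B"):
    vecs = [taxonomic_weights(d, sc.domains.profiles, sg)
            for d in datasets if d.domain == dom]
    agg[dom] = aggregate_weights(vecs)

_, xa, xb = paired_inter_weights(agg["A"], agg["B"])
res = spearman(xa, xb)
p_perm = permutation_test(xa, xb, m=1000, seed=4,
                          tail="greater" if res.rho >= 0 else "less")
print(f"inter-domain taxonomic correlation: rho = {res.rho:.3f} "
      f"(n = {res.n_enzymes} enzymes, permutation p = {p_perm:.3f})")

classes = classify_enzymes(agg["A"], agg["B"],
                           ClassificationConfig(t_high=0.667))
counts = Counter(c.label for c in classes)
print("enzyme classes:", dict(counts))

truth = sc.domains.truth
planted = ([(ec, "specific_to_A") for ec in truth.planted_specific["A"]]
           + [(ec, "specific_to_B") for ec in truth.planted_specific["B"]]
           + [(ec, "ubiquitous") for ec in truth.planted_ubiquitous])
labels = {c.ec: c.label for c in classes}
hits = sum(labels[ec] == lab for ec, lab in planted)
print(f"planted-label recovery: {hits}/{len(planted)}")
print("\nA specific enzyme is common (mean weight > 0.667) in one domain and")
print("rare (< 0.333) in the other; ubiquitous enzymes are common in both.")
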