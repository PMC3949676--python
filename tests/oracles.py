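"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive: direct double loops, dict-based
dynamic programming, exhaustive enumeration.  These functions share no code
with the package internals they check.
"""

from __future__ import annotations

import itertools
from typing import Callable, Mapping, Sequence

import numpy as np


# -- graph construction ------------------------------------------------------

def filter_one(compounds, cofactors):
    return {c for c in compounds if c.startswith("C") and c not in set(cofactors)}


def edge_oracle(reactions, cofactors) -> set[frozenset]:
    """All EC pairs with some pair of reactions sharing a filtered compound."""
    ecs = sorted({ec for r in reactions for ec in r.ec_numbers})
    edges = set()
    for a, b in itertools.combinations(ecs, 2):
        found = False
        for ra in reactions:
            if a not in ra.ec_numbers:
                continue
            ca = filter_one(ra.substrates | ra.products, cofactors)
            for rb in reactions:
                if b not in rb.ec_numbers:
                    continue
                cb = filter_one(rb.substrates | rb.products, cofactors)
                if ca & cb:
                    found = True
        if found:
            edges.add(frozenset((a, b)))
    return edges


def pathway_edge_oracle(reactions, pathway_id, members, cofactors):
    in_pw = []
    for r in reactions:
        if r.pathways:
            if pathway_id in r.pathways:
                in_pw.append(r)
        elif r.ec_numbers <= set(members):
            in_pw.append(r)
    return {e for e in edge_oracle(in_pw, cofactors)
            if e <= set(members)}


# -- weights ----------------------------------------------------------------

def taxonomic_oracle(genome_ids, profiles, enzymes):
    out = {}
    for v in enzymes:
        n = 0
        for g in genome_ids:
            if v in profiles[g].enzymes:
                n += 1
        out[v] = n / len(genome_ids)
    return out


def isoenzymatic_oracle(genome_ids, profiles, enzymes):
    out = {}
    for v in enzymes:
        counts = []
        for g in genome_ids:
            if v in profiles[g].enzymes:
                counts.append(len(set(profiles[g].enzymes[v])))
        out[v] = sum(counts) / len(counts) if counts else 0.0
    return out


def seqsim_oracle(genome_ids, profiles, enzymes, chooser, sim):
    """Mean pairwise similarity using an externally supplied representative
    chooser (so the seeded choice itself is not under test here) and an
    externally supplied similarity function."""
    out = {}
    for v in enzymes:
        seqs = []
        for g in genome_ids:
            p = profiles[g]
            if v in p.enzymes:
                seqs.append(p.sequences[chooser(v, p)])
        if len(seqs) < 2:
            continue
        sims = []
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                sims.append(sim(seqs[i], seqs[j]))
        out[v] = sum(sims) / len(sims)
    return out


# -- alignment ---------------------------------------------------------------

def gotoh_oracle(a: str, b: str, score: Callable[[str, str], float],
                 gap_open: float = 11.0, gap_extend: float = 1.0):
    """Dict-based affine-gap local alignment with the documented tie-breaks
    (diagonal > vertical > horizontal; end cell = first row-major maximum).

    Returns (score, identities, alignment_length).
    """
    NEG = float("-inf")
    open_cost = gap_open + gap_extend
    m, n = len(a), len(b)
    H = {(i, j): 0.0 for i in range(m + 1) for j in range(n + 1)}
    E = {(i, j): NEG for i in range(m + 1) for j in range(n + 1)}
    F = dict(E)
    ph, pe, pf = {}, {}, {}
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            eo, ee = H[i, j - 1] - open_cost, E[i, j - 1] - gap_extend
            E[i, j], pe[i, j] = (eo, "open") if eo >= ee else (ee, "ext")
            fo, fe = H[i - 1, j] - open_cost, F[i - 1, j] - gap_extend
            F[i, j], pf[i, j] = (fo, "open") if fo >= fe else (fe, "ext")
            diag = H[i - 1, j - 1] + score(a[i - 1], b[j - 1])
            val, p = diag, "diag"
            if F[i, j] > val:
                val, p = F[i, j], "up"
            if E[i, j] > val:
                val, p = E[i, j], "left"
            if val <= 0:
                H[i, j], ph[i, j] = 0.0, "stop"
            else:
                H[i, j], ph[i, j] = val, p
                if val > best:
                    best, bi, bj = val, i, j
    ident = length = 0
    i, j, state = bi, bj, "H"
    while True:
        if state == "H":
            p = ph.get((i, j), "stop")
            if p == "stop":
                break
            if p == "diag":
                length += 1
                ident += a[i - 1] == b[j - 1]
                i, j = i - 1, j - 1
            elif p == "up":
                state = "F"
            else:
                state = "E"
        elif state == "F":
            length += 1
            p = pf[i, j]
            i -= 1
            state = "H" if p == "open" else "F"
        else:
            length += 1
            p = pe[i, j]
            j -= 1
            state = "H" if p == "open" else "E"
    return best, ident, length


def similarity_oracle(a, b, score):
    if a == b:
        return 1.0
    if b < a:
        a, b = b, a
    _, ident, length = gotoh_oracle(a, b, score)
    return ident / length if length else 0.0


# -- statistics ---------------------------------------------------------------

def rank_avg(x: Sequence[float]) -> list[float]:
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        r = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    rx, ry = rank_avg(x), rank_avg(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) *
           sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den


def exhaustive_permutation_p(x, y, tail="greater") -> float:
    obs = spearman_oracle(x, y)
    count = total = 0
    for perm in itertools.permutations(y):
        r = spearman_oracle(x, list(perm))
        if tail == "greater" and r >= obs - 1e-12:
            count += 1
        if tail == "less" and r <= obs + 1e-12:
            count += 1
        total += 1
    return count / total


# -- compression --------------------------------------------------------------

def expand_oracle(supernodes: Mapping[str, frozenset],
                  superedges: Mapping[tuple, float]) -> dict[frozenset, float]:
    """Pairwise expansion of superedges to original node pairs."""
    out = {}
    for (sa, sb), w in superedges.items():
        if w == 0:
            continue
        if sa == sb:
            for u, v in itertools.combinations(sorted(supernodes[sa]), 2):
                out[frozenset((u, v))] = w
        else:
            for u in supernodes[sa]:
                for v in supernodes[sb]:
                    out[frozenset((u, v))] = w
    return out


def distance_oracle(q, edges_orig, edges_dec, retained, c_node=1.0):
    d = sum(q[v] * c_node for v in set(q) - set(retained))
    keys = {frozenset(k) for k in edges_orig} | {frozenset(k) for k in edges_dec}
    eo = {frozenset(k): w for k, w in edges_orig.items()}
    ed = {frozenset(k): w for k, w in edges_dec.items()}
    for key in keys:
        u, v = sorted(key)
        if u in retained and v in retained:
            d += (q[u] + q[v]) / 2 * abs(eo.get(key, 0.0) - ed.get(key, 0.0))
    return d


def exhaustive_compression_search(graph, target_cr, apply_ops, max_states=200000):
    """DFS over all operation sequences reaching cr <= target.

    ``apply_ops(state)`` must return the list of (op_name, successor_state)
    pairs plus a terminal measurement function; implemented in the test to
    use the package's own operations, so this searches the same operation
    space the greedy works in.  Returns (min_distance, max_distance) over
    all terminal states, or None if the target is unreachable.
    """
    from metaweight.compression import decompress, distance, identity_compression

    orig_size = graph.size
    start = identity_compression(graph)
    seen = set()
    best = [float("inf"), float("-inf")]
    found = [False]

    def signature(cg):
        return (frozenset(cg.supernodes.values()),
                frozenset((k, round(w, 9)) for k, w in cg.superedges.items()))

    def rec(cg):
        if len(seen) > max_states:
            raise RuntimeError("state budget exceeded")
        sig = signature(cg)
        if sig in seen:
            return
        seen.add(sig)
        if cg.size / orig_size <= target_cr + 1e-12:
            d = distance(graph, decompress(cg))
            best[0] = min(best[0], d)
            best[1] = max(best[1], d)
            found[0] = True
            return
        for _, nxt in apply_ops(cg):
            rec(nxt)

    rec(start)
    return (best[0], best[1]) if found[0] else None


def type_i_error_rate(n, n_sims, m, alpha, seed, test):
    rng = np.random.default_rng(seed)
    rejections = 0
    for s in range(n_sims):
        x = rng.random(n)
        y = rng.random(n)
        if test(x, y, m, s) < alpha:
            rejections += 1
    return rejections / n_sims
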