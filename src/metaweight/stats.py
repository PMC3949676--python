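"""Correlation, permutation tests, enzyme classification and pathway ratios.

Spearman's rank correlation is used throughout for robustness.  Because the
two domains share one graph topology and only node weights differ, shuffling
the weights over the nodes yields a topology- and distribution-preserving
null ("random graph"); the permutation test counts how often the shuffled
correlation is at least as extreme as the observed one, one-tailed on the
signed statistic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .graph import Pathway
from .weighting import AggregatedWeights, GenomeProfile

__all__ = [
    "CorrelationResult",
    "ClassificationConfig",
    "EnzymeClass",
    "spearman",
    "permutation_test",
    "enzyme_inclusion",
    "intra_enzyme_set",
    "inter_enzyme_set",
    "paired_inter_weights",
    "classify_enzymes",
    "pathway_ratios",
]

_EPS = 1e-12


@dataclass
class CorrelationResult:
    rho: float
    p_analytic: float
    n_enzymes: int
    permutation_p: float | None = None


@dataclass
class ClassificationConfig:
    """Thresholds for specific/ubiquitous calls.

    For weights ranged in [0, 1] the low threshold defaults to
    ``1 - t_high``; for the unbounded isoenzymatic weight both thresholds
    must be given explicitly (default 1 and 1).
    """

    t_high: float = 0.667
    t_low: float | None = None

    def __post_init__(self) -> None:
        if self.t_low is None:
            self.t_low = 1.0 - self.t_high
        if self.t_low <= 0 or self.t_high < self.t_low:
            raise ValueError("thresholds must satisfy 0 < t_low <= t_high")

    @classmethod
    def isoenzymatic(cls, t_high: float = 1.0, t_low: float = 1.0):
        return cls(t_high=t_high, t_low=t_low)


@dataclass(frozen=True)
class EnzymeClass:
    ec: str
    label: str  # specific_to_A | specific_to_B | ubiquitous | neither


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    # Two-sided exact p over all n! rank permutations (used for n <= 8).
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))))
    rys = ry[perms]
    rxc = rx - rx.mean()
    ryc = rys - rys.mean(axis=1, keepdims=True)
    rhos = (ryc @ rxc) / np.sqrt((rxc @ rxc) * (ryc * ryc).sum(axis=1))
    return float(np.mean(np.abs(rhos) >= abs(rho) - _EPS))


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rho (average ranks on ties) with a two-sided analytic p.

    The p-value is exact (full rank-permutation enumeration) for n <= 8 and
    the large-sample t approximation otherwise.  Constant vectors raise
    ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_rho(rx, ry)
    if x.size <= 8:
        p = _exact_p(rx, ry, rho)
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return CorrelationResult(rho=rho, p_analytic=p, n_enzymes=int(x.size))


def permutation_test(
    x: Sequence[float],
    y: Sequence[float],
    m: int = 1000,
    seed: int = 0,
    tail: str = "greater",
    exhaustive: bool = False,
) -> float:
    """One-tailed permutation p for Spearman correlation.

    One group's values are rearranged without replacement ``m`` times; the p
    is the fraction of permuted coefficients equal to or larger than the
    observed one (``tail="greater"``), or equal to or smaller
    (``tail="less"``).  With ``exhaustive=True`` all n! permutations are
    enumerated instead (n <= 8 only).  Deterministic given ``seed``.
    """
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = _rank_rho(rx, ry)
    rxc = rx - rx.mean()
    denom_x = math.sqrt(rxc @ rxc)
    if exhaustive:
        if x.size > 8:
            raise ValueError("exhaustive enumeration limited to n <= 8")
        perm_idx = np.array(list(itertools.permutations(range(x.size))))
    else:
        if m < 1:
            raise ValueError("m must be >= 1")
        rng = np.random.default_rng(seed)
        perm_idx = np.array([rng.permutation(x.size) for _ in range(m)])
    rys = ry[perm_idx]
    ryc = rys - rys.mean(axis=1, keepdims=True)
    rhos = (ryc @ rxc) / (denom_x * np.sqrt((ryc * ryc).sum(axis=1)))
    if tail == "greater":
        count = int(np.sum(rhos >= obs - _EPS))
    else:
        count = int(np.sum(rhos <= obs + _EPS))
    return count / len(perm_idx)


def intra_enzyme_set(
    dataset_genomes: Iterable[str],
    profiles: Mapping[str, GenomeProfile],
    enzymes: Iterable[str],
) -> set[str]:
    """Enzymes present in at least two genomes of the selected dataset."""
    selected = [profiles[g] for g in dataset_genomes]
    out = set()
    for v in enzymes:
        if sum(1 for p in selected if v in p.enzymes) >= 2:
            out.add(v)
    return out


def inter_enzyme_set(
    agg_a: AggregatedWeights,
    agg_b: AggregatedWeights,
) -> set[str]:
    """Enzymes with a defined non-zero mean weight in either domain."""
    nz = lambda agg: {ec for ec, w in agg.mean_values.items() if w != 0.0}
    return nz(agg_a) | nz(agg_b)


def enzyme_inclusion(mode: str, *args, **kwargs) -> set[str]:
    """Dispatch to the intra- or inter-domain enzyme inclusion rule."""
    if mode == "intra":
        return intra_enzyme_set(*args, **kwargs)
    if mode == "inter":
        return inter_enzyme_set(*args, **kwargs)
    raise ValueError(f"unknown inclusion mode {mode!r}")


def paired_inter_weights(
    agg_a: AggregatedWeights,
    agg_b: AggregatedWeights,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Paired mean-weight vectors over the inter-domain enzyme set.

    Enzymes weighted in one domain only get 0 on the missing side.
    """
    ecs = sorted(inter_enzyme_set(agg_a, agg_b))
    xa = np.array([agg_a.mean_values.get(ec, 0.0) for ec in ecs])
    xb = np.array([agg_b.mean_values.get(ec, 0.0) for ec in ecs])
    return ecs, xa, xb


def classify_enzymes(
    agg_a: AggregatedWeights,
    agg_b: AggregatedWeights,
    cfg: ClassificationConfig | None = None,
) -> list[EnzymeClass]:
    """Label enzymes specific to one domain, ubiquitous, or neither.

    Specific to A: mean_A > t_high and mean_B < t_low (symmetric for B);
    ubiquitous: both means > t_high.  An enzyme with no defined mean in a
    domain is treated as weight 0 there.
    """
    cfg = cfg or ClassificationConfig()
    ecs = sorted(set(agg_a.mean_values) | set(agg_b.mean_values))
    out = []
    for ec in ecs:
        a = agg_a.mean_values.get(ec, 0.0)
        b = agg_b.mean_values.get(ec, 0.0)
        if a > cfg.t_high and b > cfg.t_high:
            label = "ubiquitous"
        elif a > cfg.t_high and b < cfg.t_low:
            label = "specific_to_A"
        elif b > cfg.t_high and a < cfg.t_low:
            label = "specific_to_B"
        else:
            label = "neither"
        out.append(EnzymeClass(ec=ec, label=label))
    return out


def pathway_ratios(
    pathways: Sequence[Pathway],
    classes: Sequence[EnzymeClass],
    agg_a: AggregatedWeights,
    agg_b: AggregatedWeights,
    min_weighted: int = 10,
) -> pd.DataFrame:
    """Specific/ubiquitous enzyme ratios per retained pathway.

    A pathway is retained only if it has at least ``min_weighted`` enzymes
    with non-zero mean weight in *both* domains.  ``n_weighted`` counts
    member enzymes with non-zero mean weight in either domain, and the
    ratios are relative to it.
    """
    label = {c.ec: c.label for c in classes}
    rows = []
    for pw in sorted(pathways, key=lambda p: p.pathway_id):
        nz_a = {ec for ec in pw.enzymes if agg_a.mean_values.get(ec, 0.0) != 0}
        nz_b = {ec for ec in pw.enzymes if agg_b.mean_values.get(ec, 0.0) != 0}
        if len(nz_a) < min_weighted or len(nz_b) < min_weighted:
            continue
        weighted = nz_a | nz_b
        n = len(weighted)
        n_spec = sum(1 for ec in weighted
                     if label.get(ec, "neither").startswith("specific"))
        n_ubiq = sum(1 for ec in weighted if label.get(ec) == "ubiquitous")
        rows.append({
            "pathway_id": pw.pathway_id,
            "name": pw.name,
            "n_weighted": n,
            "specific_ratio": n_spec / n,
            "ubiquitous_ratio": n_ubiq / n,
        })
    return pd.DataFrame(
        rows, columns=["pathway_id", "name", "n_weighted", "specific_ratio",
                       "ubiquitous_ratio"])
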