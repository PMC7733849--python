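"""Genetic-background-effect (GBE) typology from reciprocal hybrid cohorts.

Methylation means of three cohorts — pure B6, BC (B6 dam x CAST sire) and
CB (CAST dam x B6 sire) — are compared per locus with a Kruskal-Wallis
test followed by Dunn's post hoc pairwise comparisons.  The pattern of
significant pairwise differences assigns each locus one of four
categories:

* ``maternal``          exactly one hybrid differs from B6 and the two
                        hybrids differ from each other;
* ``zygotic``           both hybrids differ from B6 but not from each other;
* ``maternal+zygotic``  both hybrids differ from B6 and from each other;
* ``none``              neither hybrid differs from B6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .methylation import MethylationTable, individual_means

__all__ = [
    "GroupedMeans",
    "GBEResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "classify_gbe",
    "gbe_analysis",
]

GROUP_LABELS = ("B6", "BC", "CB")
PAIRS = (("BC", "B6"), ("CB", "B6"), ("BC", "CB"))


@dataclass(frozen=True)
class GroupedMeans:
    """Per-individual methylation means for the three cohorts at one locus."""

    locus: str
    groups: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.groups) != set(GROUP_LABELS):
            raise ValueError(f"group labels must be exactly {GROUP_LABELS}")
        for name, vals in self.groups.items():
            if np.asarray(vals).size < 2:
                raise ValueError(f"group {name} needs n >= 2")


@dataclass(frozen=True)
class GBEResult:
    locus: str
    h_statistic: float
    kw_p: float
    dunn_z: Dict[Tuple[str, str], float]
    dunn_p_raw: Dict[Tuple[str, str], float]
    dunn_p_adj: Dict[Tuple[str, str], float]
    category: str
    direction: str  # 'hyper' | 'hypo' | 'none'

    def summary(self) -> dict:
        d = {"locus": self.locus, "H": self.h_statistic, "p": self.kw_p,
             "category": self.category, "direction": self.direction}
        for pair in PAIRS:
            d[f"p_adj[{pair[0]}-{pair[1]}]"] = self.dunn_p_adj[pair]
        return d


def kruskal_wallis(groups: Sequence[np.ndarray]) -> Tuple[float, float]:
    """Kruskal-Wallis H (midranks, tie-corrected) and chi-square p.

    Degenerate all-identical input returns (0, 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _midranks_and_ties(groups: Sequence[np.ndarray]) -> Tuple[List[np.ndarray], float, int]:
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    split, i = [], 0
    for g in groups:
        split.append(ranks[i : i + len(g)])
        i += len(g)
    return split, tie_sum, n_total


def dunn_posthoc(
    groups: Mapping[str, np.ndarray], adjustment: str = "bonferroni"
) -> Tuple[Dict[Tuple[str, str], float], Dict[Tuple[str, str], float], Dict[Tuple[str, str], float]]:
    """Dunn's z and two-sided p for each pair of groups.

    z(i, j) = (rbar_i - rbar_j) / sqrt(S2 (1/n_i + 1/n_j)) with the
    tie-corrected pooled variance
    S2 = N(N+1)/12 - sum(t^3 - t) / (12 (N - 1)).
    Adjustment: 'bonferroni' (multiply by number of pairs, capped at 1),
    'holm', or 'none'.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    split, tie_sum, n_total = _midranks_and_ties(arrays)
    s2 = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    rbar = {n: float(r.mean()) for n, r in zip(names, split)}
    sizes = {n: a.size for n, a in zip(names, arrays)}
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    z: Dict[Tuple[str, str], float] = {}
    p_raw: Dict[Tuple[str, str], float] = {}
    for a, b in pairs:
        if s2 <= 0:  # every observation tied
            z[(a, b)], p_raw[(a, b)] = 0.0, 1.0
            continue
        se = np.sqrt(s2 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        zz = (rbar[a] - rbar[b]) / se
        z[(a, b)] = float(zz)
        p_raw[(a, b)] = float(2.0 * stats.norm.sf(abs(zz)))
    m = len(pairs)
    p_adj: Dict[Tuple[str, str], float] = {}
    if adjustment == "none":
        p_adj = dict(p_raw)
    elif adjustment == "bonferroni":
        p_adj = {k: min(1.0, m * v) for k, v in p_raw.items()}
    elif adjustment == "holm":
        order = sorted(p_raw, key=p_raw.get)
        running = 0.0
        for rank, k in enumerate(order):
            running = max(running, (m - rank) * p_raw[k])
            p_adj[k] = min(1.0, running)
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    return z, p_raw, p_adj


def classify_gbe(p_adj: Mapping[Tuple[str, str], float], alpha: float = 0.05) -> str:
    """Apply the four-way decision table to the three adjusted p-values."""
    sig = {pair: p_adj[pair] < alpha for pair in PAIRS}
    bc_b6, cb_b6, bc_cb = sig[("BC", "B6")], sig[("CB", "B6")], sig[("BC", "CB")]
    if not bc_b6 and not cb_b6:
        return "none"
    if bc_b6 and cb_b6:
        return "maternal+zygotic" if bc_cb else "zygotic"
    # exactly one hybrid differs from B6
    if bc_cb:
        return "maternal"
    # one vs-B6 difference but hybrids indistinguishable: borderline power;
    # treated as zygotic evidence (both hybrids carry the haploid genome).
    return "zygotic"


def _direction(groups: Mapping[str, np.ndarray]) -> str:
    hybrids = np.concatenate([np.asarray(groups["BC"]), np.asarray(groups["CB"])])
    diff = float(np.median(hybrids) - np.median(np.asarray(groups["B6"])))
    if diff > 0:
        return "hyper"
    if diff < 0:
        return "hypo"
    return "none"


def analyze_locus(gm: GroupedMeans, alpha: float = 0.05, adjustment: str = "bonferroni") -> GBEResult:
    arrays = [np.asarray(gm.groups[n], dtype=float) for n in GROUP_LABELS]
    h, p = kruskal_wallis(arrays)
    z, p_raw, p_adj = dunn_posthoc({n: gm.groups[n] for n in GROUP_LABELS}, adjustment)
    # canonicalize pair keys to the documented order
    zc = {}
    for pair in PAIRS:
        zc[pair] = z[pair] if pair in z else -z[(pair[1], pair[0])]
    pr = {pair: p_raw.get(pair, p_raw.get((pair[1], pair[0]))) for pair in PAIRS}
    pa = {pair: p_adj.get(pair, p_adj.get((pair[1], pair[0]))) for pair in PAIRS}
    category = classify_gbe(pa, alpha)
    direction = _direction(gm.groups) if category != "none" else "none"
    return GBEResult(gm.locus, h, p, zc, pr, pa, category, direction)


def gbe_analysis(
    table: MethylationTable,
    group_assignment: Mapping[str, str],
    alpha: float = 0.05,
    adjustment: str = "bonferroni",
) -> List[GBEResult]:
    """Run the per-locus GBE classification over a methylation table.

    ``group_assignment`` maps individual id -> B6 | BC | CB.
    """
    results = []
    for locus in table.loci:
        means = individual_means(table, locus)
        groups: Dict[str, List[float]] = {g: [] for g in GROUP_LABELS}
        for ind, m in means.items():
            g = group_assignment.get(str(ind))
            if g in groups:
                groups[g].append(float(m))
        gm = GroupedMeans(locus, {g: np.asarray(v) for g, v in groups.items()})
        results.append(analyze_locus(gm, alpha=alpha, adjustment=adjustment))
    return results
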