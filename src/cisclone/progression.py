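"""Clonality-based ordering of driver-gene groups (tumor progression model).

Detected CISs are pooled into gene families (remaining CISs become
singleton groups) and groups hit in fewer than a minimum number of tumors
are dropped. Within every tumor carrying two groups, the group whose
insertions have the higher LP-based clonality score is taken to be the
earlier event; across tumors this yields a sign test: under no consistent
order, wins split Binomial(n, 1/2). Significant comparisons become directed
edges from the consistently more clonal (earlier) group to the later one.
LP scores are only ever compared within a tumor, never across tumors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .network import PRESENCE_MIN_LP


@dataclass
class CISGroup:
    name: str
    members: list[str]  # CIS ids
    n_tumors: int


@dataclass
class OrderComparison:
    group_a: str
    group_b: str
    wins_a: int
    wins_b: int
    ties: int
    p_value: float | None  # None when no informative tumor exists

    @property
    def n_informative(self) -> int:
        return self.wins_a + self.wins_b

    @property
    def untestable(self) -> bool:
        return self.p_value is None


@dataclass
class ProgressionEdge:
    parent: str  # consistently more clonal (earlier) group
    child: str
    wins_parent: int
    wins_child: int
    p_value: float

    @property
    def fraction_label(self) -> str:
        return f"{self.wins_parent}/{self.wins_child}"

    @property
    def weight(self) -> float:
        return float(-np.log10(max(self.p_value, 1e-300)))


def group_cis(
    matrix: pd.DataFrame,
    family_map: dict[str, list[str]],
    min_tumors: int = 10,
) -> list[CISGroup]:
    """Pool CIS columns into named families; ungrouped CISs become singletons.

    ``family_map`` maps family name -> member CIS ids. A CIS assigned to two
    families is a configuration error. n_tumors counts distinct tumors with
    presence in any member (a tumor hit in two members counts once); groups
    below ``min_tumors`` are dropped.
    """
    if min_tumors < 1:
        raise ValueError("min_tumors must be >= 1")
    seen: dict[str, str] = {}
    for fam, members in family_map.items():
        for m in members:
            if m in seen:
                raise ValueError(f"CIS {m} assigned to both {seen[m]} and {fam}")
            seen[m] = fam
    pres = matrix >= PRESENCE_MIN_LP
    groups = []
    for fam, members in family_map.items():
        cols = [m for m in members if m in matrix.columns]
        if not cols:
            continue
        n = int(pres[cols].any(axis=1).sum())
        groups.append(CISGroup(fam, cols, n))
    for cis in matrix.columns:
        if cis not in seen:
            groups.append(CISGroup(cis, [cis], int(pres[cis].sum())))
    return [g for g in groups if g.n_tumors >= min_tumors]


def group_scores(matrix: pd.DataFrame, groups: list[CISGroup]) -> pd.DataFrame:
    """Tumor x group clonality scores: max member score per tumor (0 = absent)."""
    data = {g.name: matrix[g.members].max(axis=1) for g in groups}
    return pd.DataFrame(data, index=matrix.index)


def clonality_score(matrix_row: pd.Series, group: CISGroup) -> int:
    """Clonality score of one tumor for one group (max LP over members).

    The caller must ensure the tumor actually has an insertion in the group.
    """
    score = int(matrix_row[group.members].max())
    if score < PRESENCE_MIN_LP:
        raise ValueError(f"group {group.name} absent in this tumor")
    return score


def exact_binomial_two_sided(wins: int, n: int) -> float:
    """Sign-test p: 2 x min(P(X >= wins), P(X <= wins)) under Bin(n, 1/2), capped at 1."""
    tail_ge = float(binom.sf(wins - 1, n, 0.5))
    tail_le = float(binom.cdf(wins, n, 0.5))
    return min(1.0, 2.0 * min(tail_ge, tail_le))


def compare_groups(
    scores: pd.DataFrame, a: str, b: str, alternative: str = "two-sided"
) -> OrderComparison:
    """Sign test of within-tumor clonality between two groups.

    Over tumors where both groups are present, count the tumors where a's
    score exceeds b's and vice versa; ties are excluded. The p-value is the
    exact binomial test of the win counts at p = 1/2 (two-sided by default;
    ``alternative='greater'`` tests a more clonal than b). No informative
    tumors -> untestable (p None).
    """
    for g in (a, b):
        if g not in scores.columns:
            raise ValueError(f"unknown group {g!r}")
    if a == b:
        raise ValueError("compare_groups requires two distinct groups")
    sa = scores[a].to_numpy()
    sb = scores[b].to_numpy()
    both = (sa >= PRESENCE_MIN_LP) & (sb >= PRESENCE_MIN_LP)
    wins_a = int(np.sum(both & (sa > sb)))
    wins_b = int(np.sum(both & (sa < sb)))
    ties = int(both.sum()) - wins_a - wins_b
    n = wins_a + wins_b
    if n == 0:
        return OrderComparison(a, b, wins_a, wins_b, ties, None)
    if alternative == "two-sided":
        p = exact_binomial_two_sided(wins_a, n)
    elif alternative == "greater":
        p = float(binom.sf(wins_a - 1, n, 0.5))
    else:
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    return OrderComparison(a, b, wins_a, wins_b, ties, p)


def all_comparisons(
    scores: pd.DataFrame, alternative: str = "two-sided"
) -> list[OrderComparison]:
    from itertools import combinations

    return [
        compare_groups(scores, a, b, alternative=alternative)
        for a, b in combinations(scores.columns, 2)
    ]


def progression_graph(
    comparisons: list[OrderComparison],
    alpha: float = 0.05,
    correction: str | None = None,
) -> tuple[list[ProgressionEdge], bool]:
    """Directed progression edges from significant clonality comparisons.

    Each comparison with p <= alpha yields an edge pointing from the group
    with more wins (more clonal, hence earlier) to the other; untestable
    pairs and exact win ties are omitted. ``correction='bh'`` optionally
    applies Benjamini-Hochberg across the comparisons first (off by
    default). Returns the edges and whether the resulting graph is acyclic
    (reported, not enforced).
    """
    import networkx as nx

    testable = [c for c in comparisons if not c.untestable]
    pvals = [c.p_value for c in testable]
    if correction == "bh" and pvals:
        from statsmodels.stats.multitest import multipletests

        pvals = list(multipletests(pvals, method="fdr_bh")[1])
    edges = []
    for c, p in zip(testable, pvals):
        if p > alpha or c.wins_a == c.wins_b:
            continue
        if c.wins_a > c.wins_b:
            edges.append(ProgressionEdge(c.group_a, c.group_b, c.wins_a, c.wins_b, float(p)))
        else:
            edges.append(ProgressionEdge(c.group_b, c.group_a, c.wins_b, c.wins_a, float(p)))
    g = nx.DiGraph()
    g.add_edges_from((e.parent, e.child) for e in edges)
    acyclic = nx.is_directed_acyclic_graph(g)
    return edges, acyclic


def comparisons_table(comparisons: list[OrderComparison]) -> pd.DataFrame:
    rows = [
        (c.group_a, c.group_b, c.wins_a, c.wins_b, c.ties, c.p_value) for c in comparisons
    ]
    return pd.DataFrame(rows, columns=["group_a", "group_b", "wins_a", "wins_b", "ties", "p"])


def edges_table(edges: list[ProgressionEdge]) -> pd.DataFrame:
    rows = [
        (e.parent, e.child, e.wins_parent, e.wins_child, e.fraction_label, e.p_value)
        for e in edges
    ]
    return pd.DataFrame(
        rows, columns=["parent", "child", "wins_parent", "wins_child", "fraction", "p"]
    )


def edges_to_graphml(edges: list[ProgressionEdge], path) -> None:
    import networkx as nx

    g = nx.DiGraph()
    for e in edges:
        g.add_edge(
            e.parent, e.child, fraction=e.fraction_label, p=e.p_value, weight=e.weight
        )
    nx.write_graphml(g, path)
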