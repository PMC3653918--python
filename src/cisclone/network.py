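"""Tumor x CIS incidence and co-occurrence / mutual-exclusivity testing.

Each tumor-CIS cell carries a clonality score (the maximum LP count among
that tumor's insertions inside the CIS; 0 if absent). Pairwise association
is tested with one-sided exact hypergeometric (Fisher) tails in both
directions — enrichment of the overlap for co-occurrence, depletion for
mutual exclusivity — with Benjamini-Hochberg correction pooled across both
one-sided families. Family-level exclusivity is assessed with a permutation
null that shuffles each member's presence column independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, kstest
from statsmodels.stats.multitest import multipletests

#: presence requires a clonality score at this LP minimum (post-filter floor)
PRESENCE_MIN_LP = 2


def build_incidence(
    insertions: pd.DataFrame, cis_list, tumors: pd.DataFrame
) -> pd.DataFrame:
    """Tumor x CIS matrix of clonality scores (max lp_count inside the CIS).

    Rows cover every tumor in ``tumors``; a tumor with no insertion in a CIS
    scores 0. Presence is score >= 2 (the single-LP filter floor).
    """
    ids = [c.cis_id for c in cis_list]
    matrix = pd.DataFrame(
        0, index=pd.Index(tumors["tumor_id"], name="tumor_id"), columns=ids, dtype=int
    )
    for cis in cis_list:
        inside = insertions[
            (insertions["chrom"] == cis.chrom)
            & (insertions["position"] >= cis.start)
            & (insertions["position"] <= cis.end)
        ]
        if inside.empty:
            continue
        scores = inside.groupby("tumor_id")["lp_count"].max()
        scores = scores[scores.index.isin(matrix.index)]
        matrix.loc[scores.index, cis.cis_id] = scores.astype(int)
    return matrix


def presence(matrix: pd.DataFrame) -> pd.DataFrame:
    return matrix >= PRESENCE_MIN_LP


@dataclass
class AssociationEdge:
    cis_a: str
    cis_b: str
    n11: int
    n10: int
    n01: int
    n00: int
    p_cooccurrence: float
    p_exclusivity: float
    direction: str | None  # "co-occurring" | "mutually-exclusive" | None
    p_value: float | None
    q_value: float | None = None
    untestable: bool = False

    @property
    def table(self):
        return ((self.n11, self.n10), (self.n01, self.n00))


def _pair_counts(pres: pd.DataFrame, a: str, b: str):
    pa = pres[a].to_numpy()
    pb = pres[b].to_numpy()
    n11 = int(np.sum(pa & pb))
    n10 = int(np.sum(pa & ~pb))
    n01 = int(np.sum(~pa & pb))
    n00 = int(np.sum(~pa & ~pb))
    return n11, n10, n01, n00


def test_pair(matrix: pd.DataFrame, a: str, b: str) -> AssociationEdge:
    """Exact one-sided association tests for one CIS pair.

    Conditions on the margins: with N tumors, m_a and m_b presences and k
    overlapping, the co-occurrence p is P(K >= k) and the exclusivity p is
    P(K <= k) under the hypergeometric null. The reported direction is the
    smaller one-sided tail; both are retained. A CIS present in zero or all
    tumors gives an untestable edge.
    """
    if a == b:
        raise ValueError("test_pair requires two distinct CISs")
    pres = presence(matrix[[a, b]])
    n11, n10, n01, n00 = _pair_counts(pres, a, b)
    n = n11 + n10 + n01 + n00
    m_a, m_b = n11 + n10, n11 + n01
    if m_a in (0, n) or m_b in (0, n):
        return AssociationEdge(a, b, n11, n10, n01, n00, 1.0, 1.0, None, None, untestable=True)
    p_co = float(hypergeom.sf(n11 - 1, n, m_a, m_b))
    p_ex = float(hypergeom.cdf(n11, n, m_a, m_b))
    if p_co <= p_ex:
        direction, p = "co-occurring", p_co
    else:
        direction, p = "mutually-exclusive", p_ex
    return AssociationEdge(a, b, n11, n10, n01, n00, p_co, p_ex, direction, p)


def build_network(
    matrix: pd.DataFrame, alpha: float = 0.05
) -> list[AssociationEdge]:
    """Test all CIS pairs and keep BH-significant edges.

    Both one-sided p-value families are pooled into a single BH correction;
    an edge survives if the q-value of its reported direction is <= alpha.
    Degenerate (untestable) pairs are excluded before correction. Edge
    weight for display is -log10(q).
    """
    cols = list(matrix.columns)
    if len(cols) < 2:
        raise ValueError("need at least two CISs")
    edges = [test_pair(matrix, a, b) for a, b in combinations(cols, 2)]
    testable = [e for e in edges if not e.untestable]
    if not testable:
        return []
    pooled = np.array([[e.p_cooccurrence, e.p_exclusivity] for e in testable]).ravel()
    q = multipletests(pooled, method="fdr_bh")[1].reshape(-1, 2)
    kept = []
    for e, (q_co, q_ex) in zip(testable, q):
        e.q_value = float(q_co if e.direction == "co-occurring" else q_ex)
        if e.q_value <= alpha:
            kept.append(e)
    return kept


def edges_table(edges: list[AssociationEdge]) -> pd.DataFrame:
    rows = [
        (e.cis_a, e.cis_b, e.direction, e.n11, e.n10, e.n01, e.n00, e.p_value, e.q_value)
        for e in edges
    ]
    return pd.DataFrame(
        rows, columns=["a", "b", "direction", "n11", "n10", "n01", "n00", "p", "q"]
    )


def edges_to_graphml(edges: list[AssociationEdge], path) -> None:
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        weight = -np.log10(max(e.q_value, 1e-300))
        g.add_edge(e.cis_a, e.cis_b, direction=e.direction, q=e.q_value, weight=float(weight))
    nx.write_graphml(g, path)


def family_pattern(
    matrix: pd.DataFrame,
    families: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Within-family exclusivity summaries.

    For each family: tumors hitting >= 1 member, tumors hitting >= 2
    members, and a permutation p-value for the >= 2-member overlap being
    LOWER than expected when each member's presence column is shuffled
    independently (margins preserved). Families with fewer than two members
    present in the matrix are untestable.
    """
    rng = np.random.default_rng(seed)
    pres = presence(matrix)
    rows = []
    for name, members in families.items():
        cols = [m for m in members if m in pres.columns]
        if len(cols) < 2:
            rows.append((name, len(cols), None, None, None, True))
            continue
        block = pres[cols].to_numpy()
        n_ge1 = int((block.sum(axis=1) >= 1).sum())
        observed = int((block.sum(axis=1) >= 2).sum())
        count_le = 0
        perm = block.copy()
        for _ in range(n_perm):
            for j in range(perm.shape[1]):
                rng.shuffle(perm[:, j])
            if int((perm.sum(axis=1) >= 2).sum()) <= observed:
                count_le += 1
        p = (1 + count_le) / (n_perm + 1)
        rows.append((name, len(cols), n_ge1, observed, p, False))
    return pd.DataFrame(
        rows,
        columns=["family", "n_members", "n_ge1", "n_ge2", "p_exclusive", "untestable"],
    )


def uniformity_check(pvalues) -> float:
    """KS p-value against Uniform(0,1); used by null-calibration suites."""
    return float(kstest(np.asarray(pvalues), "uniform").pvalue)


def genotype_association(
    matrix: pd.DataFrame,
    tumors: pd.DataFrame,
    stratum_key: str = "genotype",
    comparisons: list[tuple] | None = None,
) -> pd.DataFrame:
    """Per-CIS association with genotype or strain background.

    Comparisons follow the matched-cohort design: for ``genotype``, wild
    type versus the engineered model within each strain; for ``strain``,
    the wild-type cohorts of the two strains against each other. Each CIS
    gets a two-sided exact test on the 2x2 stratum x presence table, with
    BH correction across CISs within a comparison.
    """
    if stratum_key not in ("genotype", "strain"):
        raise ValueError("stratum_key must be 'genotype' or 'strain'")
    meta = tumors.set_index("tumor_id")
    pres = presence(matrix)
    if comparisons is None:
        comparisons = _default_comparisons(tumors, stratum_key)
    if not comparisons:
        raise ValueError(f"fewer than two {stratum_key} levels to compare")
    from scipy.stats import fisher_exact

    rows = []
    for label, sel_a, sel_b in comparisons:
        ids_a = [t for t in meta.index[sel_a(meta)] if t in pres.index]
        ids_b = [t for t in meta.index[sel_b(meta)] if t in pres.index]
        pvals = []
        recs = []
        for cis in pres.columns:
            k_a = int(pres.loc[ids_a, cis].sum())
            k_b = int(pres.loc[ids_b, cis].sum())
            table = [[k_a, len(ids_a) - k_a], [k_b, len(ids_b) - k_b]]
            p = float(fisher_exact(table, alternative="two-sided")[1])
            pvals.append(p)
            recs.append((label, cis, k_a, len(ids_a), k_b, len(ids_b), p))
        qvals = multipletests(pvals, method="fdr_bh")[1]
        rows.extend([(*r, float(q)) for r, q in zip(recs, qvals)])
    return pd.DataFrame(
        rows,
        columns=["comparison", "cis", "hits_a", "n_a", "hits_b", "n_b", "p", "q"],
    )


def _default_comparisons(tumors: pd.DataFrame, stratum_key: str):
    comparisons = []
    if stratum_key == "genotype":
        for strain in sorted(tumors["strain"].unique()):
            genos = sorted(tumors.loc[tumors["strain"] == strain, "genotype"].unique())
            non_wt = [g for g in genos if g != "wt"]
            if "wt" in genos and non_wt:
                for g in non_wt:
                    comparisons.append(
                        (
                            f"{strain}: wt vs {g}",
                            (lambda m, s=strain: (m["strain"] == s) & (m["genotype"] == "wt")),
                            (lambda m, s=strain, g=g: (m["strain"] == s) & (m["genotype"] == g)),
                        )
                    )
    else:
        strains = sorted(tumors.loc[tumors["genotype"] == "wt", "strain"].unique())
        for s_a, s_b in combinations(strains, 2):
            comparisons.append(
                (
                    f"wt: {s_a} vs {s_b}",
                    (lambda m, s=s_a: (m["strain"] == s) & (m["genotype"] == "wt")),
                    (lambda m, s=s_b: (m["strain"] == s) & (m["genotype"] == "wt")),
                )
            )
    return comparisons
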