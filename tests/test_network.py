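"""Incidence building and exact co-occurrence / exclusivity testing."""

import numpy as np
import pandas as pd
import pytest

from cisclone import (
    build_incidence,
    build_network,
    family_pattern,
    genotype_association,
)
from cisclone.network import test_pair as pair_test
from cisclone.cis import CISRegion
from cisclone.network import uniformity_check

from conftest import make_insertions
from oracles import hypergeom_tail_ge, hypergeom_tail_le


def _cis(chrom, center, name=None):
    return CISRegion(chrom, center - 5_000, center + 5_000, center, 30_000.0, 0, 0, 2.0)


def _matrix_from_presence(presence: np.ndarray, columns) -> pd.DataFrame:
    # presence flag -> clonality score 5, absence -> 0
    return pd.DataFrame(
        np.where(presence, 5, 0),
        index=[f"T{i}" for i in range(len(presence))],
        columns=columns,
    )


class TestBuildIncidence:
    def test_score_is_max_lp_among_insertions_in_cis(self):
        ins = make_insertions(
            [("T1", "chr1", 999_000, "+", 3, 3), ("T1", "chr1", 1_001_000, "-", 7, 9)]
        )
        tumors = pd.DataFrame({"tumor_id": ["T1"], "strain": "s", "genotype": "wt"})
        cis = _cis("chr1", 1_000_000)
        matrix = build_incidence(ins, [cis], tumors)
        assert matrix.loc["T1", cis.cis_id] == 7

    def test_tumor_without_cis_insertions_has_all_absent_row(self):
        ins = make_insertions([("T1", "chr1", 5_000_000, "+", 3, 3)])
        tumors = pd.DataFrame(
            {"tumor_id": ["T1", "T2"], "strain": "s", "genotype": "wt"}
        )
        matrix = build_incidence(ins, [_cis("chr1", 1_000_000)], tumors)
        assert (matrix.loc["T2"] == 0).all()
        assert (matrix.loc["T1"] == 0).all()  # insertion outside the CIS window

    def test_empty_cis_list_is_a_valid_empty_matrix(self):
        ins = make_insertions([("T1", "chr1", 1_000_000, "+", 3, 3)])
        tumors = pd.DataFrame({"tumor_id": ["T1"], "strain": "s", "genotype": "wt"})
        matrix = build_incidence(ins, [], tumors)
        assert matrix.shape == (1, 0)

    def test_matrix_matches_simulated_truth(self, small_cohort):
        from cisclone import call_insertions, filter_single_lp

        config, fragments, truth = small_cohort
        ins = filter_single_lp(call_insertions(fragments)).insertions
        cis_list = [
            CISRegion(l.chrom, *l.interval, l.center, 30_000.0, 0, 0, 1.0)
            for l in config.loci
        ]
        matrix = build_incidence(ins, cis_list, truth.tumors)
        # truth-derived incidence: planted events with lp >= 2 inside the window
        for locus, cis in zip(config.loci, cis_list):
            ev = truth.events[(truth.events["locus"] == locus.name) & (truth.events["lp_count"] >= 2)]
            expected = set(ev["tumor_id"])
            # background can add extra presences inside the window but cannot
            # remove planted ones
            present = set(matrix.index[matrix[cis.cis_id] >= 2])
            assert expected <= present


class TestTestPair:
    def test_one_sided_tails_match_exact_enumeration(self):
        # all tumors overlap: n11=10, margins 10/10 of 100
        presence = np.zeros((100, 2), dtype=bool)
        presence[:10] = True
        edge = pair_test(_matrix_from_presence(presence, ["A", "B"]), "A", "B")
        p_co_oracle = float(hypergeom_tail_ge(10, 100, 10, 10))
        p_ex_oracle = float(hypergeom_tail_le(10, 100, 10, 10))
        assert edge.p_cooccurrence == pytest.approx(p_co_oracle, rel=1e-10)
        assert edge.p_exclusivity == pytest.approx(p_ex_oracle, rel=1e-10)
        assert edge.direction == "co-occurring"

    def test_zero_overlap_prefers_exclusivity_direction(self):
        presence = np.zeros((100, 2), dtype=bool)
        presence[:30, 0] = True
        presence[30:70, 1] = True
        edge = pair_test(_matrix_from_presence(presence, ["A", "B"]), "A", "B")
        assert edge.n11 == 0
        assert edge.p_exclusivity < edge.p_cooccurrence
        assert edge.direction == "mutually-exclusive"

    @pytest.mark.parametrize(
        "n11,n10,n01,n00",
        [(3, 5, 2, 10), (0, 4, 4, 12), (6, 0, 0, 14), (2, 2, 2, 2)],
    )
    def test_one_sided_tails_overlap_at_observed_table(self, n11, n10, n01, n00):
        # P(K >= k) + P(K <= k) = 1 + P(K = k) >= 1 for every 2x2 table
        N, ma, mb = n11 + n10 + n01 + n00, n11 + n10, n11 + n01
        p_ge = hypergeom_tail_ge(n11, N, ma, mb)
        p_le = hypergeom_tail_le(n11, N, ma, mb)
        assert p_ge + p_le >= 1
        rows = np.zeros((N, 2), dtype=bool)
        rows[:n11] = True
        rows[n11 : n11 + n10, 0] = True
        rows[n11 + n10 : n11 + n10 + n01, 1] = True
        edge = pair_test(_matrix_from_presence(rows, ["A", "B"]), "A", "B")
        assert edge.p_cooccurrence + edge.p_exclusivity >= 1.0 - 1e-12
        assert edge.p_cooccurrence == pytest.approx(float(p_ge), rel=1e-10)
        assert edge.p_exclusivity == pytest.approx(float(p_le), rel=1e-10)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(0)
        presence = rng.random((80, 2)) < 0.3
        m = _matrix_from_presence(presence, ["A", "B"])
        ab, ba = pair_test(m, "A", "B"), pair_test(m, "B", "A")
        assert ab.p_cooccurrence == pytest.approx(ba.p_cooccurrence, rel=1e-12)
        assert ab.p_exclusivity == pytest.approx(ba.p_exclusivity, rel=1e-12)
        assert (ab.n11, ab.n10, ab.n01) == (ba.n11, ba.n01, ba.n10)

    def test_degenerate_margin_is_untestable(self):
        presence = np.zeros((50, 2), dtype=bool)
        presence[:, 0] = True  # present in all tumors
        presence[:10, 1] = True
        edge = pair_test(_matrix_from_presence(presence, ["A", "B"]), "A", "B")
        assert edge.untestable

    def test_all_absent_tumors_change_only_n00(self):
        presence = np.zeros((60, 2), dtype=bool)
        presence[:20, 0] = True
        presence[20:40, 1] = True
        full = pair_test(_matrix_from_presence(presence, ["A", "B"]), "A", "B")
        trimmed = pair_test(_matrix_from_presence(presence[:50], ["A", "B"]), "A", "B")
        assert (full.n11, full.n10, full.n01) == (trimmed.n11, trimmed.n10, trimmed.n01)
        assert full.n00 == trimmed.n00 + 10
        assert full.direction == trimmed.direction == "mutually-exclusive"


class TestBuildNetwork:
    def test_planted_exclusive_pair_recovered(self):
        rng = np.random.default_rng(8)
        n = 600
        a = rng.random(n) < 0.4
        b = (~a) & (rng.random(n) < 0.67)  # ~40% marginal, never with a
        presence = np.stack([a, b], axis=1)
        edges = build_network(_matrix_from_presence(presence, ["A", "B"]), alpha=0.05)
        assert len(edges) == 1
        assert edges[0].direction == "mutually-exclusive"
        assert edges[0].q_value <= 0.05

    def test_null_presence_controls_false_edges(self):
        # 20 independent CISs, p=0.3, 600 tumors: P(any BH-significant edge)
        # stays near alpha over replicates
        rng = np.random.default_rng(21)
        n_rep, hits = 60, 0
        for _ in range(n_rep):
            presence = rng.random((600, 20)) < 0.3
            cols = [f"C{j}" for j in range(20)]
            edges = build_network(_matrix_from_presence(presence, cols), alpha=0.05)
            hits += bool(edges)
        rate = hits / n_rep
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_single_pair_alpha_one_always_reported(self):
        presence = np.zeros((30, 2), dtype=bool)
        presence[:10, 0] = True
        presence[5:20, 1] = True
        edges = build_network(_matrix_from_presence(presence, ["A", "B"]), alpha=1.0)
        assert len(edges) == 1

    def test_q_values_monotone_in_p(self):
        rng = np.random.default_rng(5)
        presence = rng.random((200, 8)) < 0.35
        cols = [f"C{j}" for j in range(8)]
        edges = build_network(_matrix_from_presence(presence, cols), alpha=1.0)
        ordered = sorted(edges, key=lambda e: e.p_value)
        qs = [e.q_value for e in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))


class TestFamilyPattern:
    def test_perfectly_exclusive_family_has_tiny_p(self):
        rng = np.random.default_rng(3)
        n = 400
        a = rng.random(n) < 0.4
        b = (~a) & (rng.random(n) < 0.5)
        presence = np.stack([a, b], axis=1)
        m = _matrix_from_presence(presence, ["A", "B"])
        out = family_pattern(m, {"fam": ["A", "B"]}, n_perm=999, seed=0)
        assert out.loc[0, "n_ge2"] == 0
        assert out.loc[0, "p_exclusive"] <= 0.001 + 1e-9

    def test_single_member_family_untestable(self):
        m = _matrix_from_presence(np.ones((10, 1), dtype=bool), ["A"])
        out = family_pattern(m, {"solo": ["A"]}, n_perm=100, seed=0)
        assert bool(out.loc[0, "untestable"])

    def test_independent_members_give_uniform_p(self):
        # null calibration: permutation p over replicates is ~Uniform(0,1)
        rng = np.random.default_rng(17)
        ps = []
        for rep in range(100):
            presence = rng.random((120, 3)) < 0.4
            m = _matrix_from_presence(presence, ["A", "B", "C"])
            out = family_pattern(m, {"fam": ["A", "B", "C"]}, n_perm=199, seed=rep)
            ps.append(out.loc[0, "p_exclusive"])
        assert uniformity_check(ps) > 0.01


class TestGenotypeAssociation:
    @staticmethod
    def _tumors(n_a, n_b):
        return pd.DataFrame(
            {
                "tumor_id": [f"T{i}" for i in range(n_a + n_b)],
                "strain": "FVB",
                "genotype": ["wt"] * n_a + ["Pten+/-"] * n_b,
            }
        )

    def test_stratum_specific_cis_detected(self):
        presence = np.zeros((200, 1), dtype=bool)
        presence[:20] = True  # 20/100 wt vs 0/100 mutant
        m = _matrix_from_presence(presence, ["A"])
        out = genotype_association(m, self._tumors(100, 100), "genotype")
        assert out.loc[0, "p"] < 1e-4
        assert out.loc[0, "q"] <= 0.05

    def test_identical_rates_give_p_one(self):
        presence = np.zeros((200, 1), dtype=bool)
        presence[:30] = True
        presence[100:130] = True
        m = _matrix_from_presence(presence, ["A"])
        out = genotype_association(m, self._tumors(100, 100), "genotype")
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_single_stratum_rejected(self):
        m = _matrix_from_presence(np.ones((4, 1), dtype=bool), ["A"])
        tumors = pd.DataFrame(
            {"tumor_id": [f"T{i}" for i in range(4)], "strain": "FVB", "genotype": "wt"}
        )
        with pytest.raises(ValueError, match="levels"):
            genotype_association(m, tumors, "genotype")

    def test_no_planted_effect_yields_no_significant_cis(self):
        # replicated null: false discovery of a genotype-specific CIS is rare
        rng = np.random.default_rng(30)
        n_rep, any_hit = 40, 0
        tumors = self._tumors(100, 100)
        for _ in range(n_rep):
            presence = rng.random((200, 10)) < 0.25
            m = _matrix_from_presence(presence, [f"C{j}" for j in range(10)])
            out = genotype_association(m, tumors, "genotype")
            any_hit += bool((out["q"] <= 0.05).any())
        assert any_hit / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)
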