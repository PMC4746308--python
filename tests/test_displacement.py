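"""Pathway-gap detection and displacement-candidate ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import build_genome
from quinrec.displacement import (
    PathwayGap,
    ProfileEvidence,
    co_occurrence_check,
    colocalization,
    find_gaps,
    fusion_scan,
    profile_match,
    rank_candidates,
)
from quinrec.genome_io import DomainHit
from quinrec.pathway_recon import ABSENT, COMPLETE, INCOMPLETE, PathwayCall


def _call(genome, pid, missing, all_roles):
    present = tuple(r for r in all_roles if r not in missing)
    status = (
        COMPLETE if not missing else ABSENT if not present else INCOMPLETE
    )
    return PathwayCall(genome, pid, status, present, tuple(missing))


ROLES = ["R1", "R2", "R3"]


class TestFindGaps:
    def test_single_missing_role_becomes_gap(self):
        calls = [
            _call("g1", "P", ["R2"], ROLES),
            _call("g2", "P", [], ROLES),
            _call("g3", "P", [], ROLES),
        ]
        gaps = find_gaps(calls)
        assert len(gaps) == 1
        assert gaps[0].role_name == "R2"
        assert gaps[0].gap_genomes == {"g1"}
        assert gaps[0].background_genomes == {"g2", "g3"}

    def test_all_complete_yields_no_gaps(self):
        calls = [_call(g, "P", [], ROLES) for g in ("g1", "g2")]
        assert find_gaps(calls) == []

    def test_multi_missing_genomes_excluded_by_max_missing(self):
        calls = [
            _call("g1", "P", ["R1", "R2"], ROLES),
            _call("g2", "P", ["R2"], ROLES),
            _call("g3", "P", [], ROLES),
        ]
        gaps = find_gaps(calls, max_missing=1)
        assert [(g.role_name, set(g.gap_genomes)) for g in gaps] == [
            ("R2", {"g2"})
        ]
        gaps2 = find_gaps(calls, max_missing=2)
        assert {g.role_name: set(g.gap_genomes) for g in gaps2} == {
            "R1": {"g1"}, "R2": {"g1", "g2"},
        }

    @pytest.mark.parametrize("seed", range(3))
    def test_random_calls_match_filter_oracle(self, seed):
        rng = np.random.default_rng(seed)
        calls = []
        for i in range(12):
            missing = [r for r in ROLES if rng.random() < 0.3]
            calls.append(_call(f"g{i:02d}", "P", missing, ROLES))
        gaps = {(g.role_name): g for g in find_gaps(calls, max_missing=1)}
        for role in ROLES:
            expected = {
                c.genome_id for c in calls
                if role in c.missing_roles and len(c.missing_roles) <= 1
            }
            if expected:
                assert gaps[role].gap_genomes == expected
            else:
                assert role not in gaps


def _matrix(rows, genomes):
    return pd.DataFrame(rows, columns=genomes).astype(bool)


class TestProfileMatch:
    def test_perfect_profile_p_equals_inverse_binomial(self):
        genomes = [f"g{i:02d}" for i in range(25)]
        gap = PathwayGap("P", "R", frozenset(genomes[:5]),
                         frozenset(genomes[5:]))
        matrix = pd.DataFrame(
            [[g in genomes[:5] for g in genomes]], index=["cand"],
            columns=genomes,
        )
        (ev,) = profile_match(gap, matrix)
        assert ev.exact_match
        assert ev.p_value == pytest.approx(1 / math.comb(25, 5))

    def test_ubiquitous_family_scores_p_one(self):
        genomes = ["g1", "g2", "g3", "g4"]
        gap = PathwayGap("P", "R", frozenset(genomes[:2]),
                         frozenset(genomes[2:]))
        matrix = pd.DataFrame([[True] * 4], index=["fam"], columns=genomes)
        (ev,) = profile_match(gap, matrix)
        assert not ev.exact_match
        assert ev.p_value == pytest.approx(1.0)

    def test_p_matches_hypergeometric_summation_oracle(self):
        rng = np.random.default_rng(2)
        genomes = [f"g{i}" for i in range(12)]
        gap = PathwayGap("P", "R", frozenset(genomes[:4]),
                         frozenset(genomes[4:]))
        for _ in range(10):
            row = rng.random(12) < 0.5
            matrix = pd.DataFrame([row], index=["fam"], columns=genomes)
            (ev,) = profile_match(gap, matrix)
            k, K = ev.n_present_in_gap, ev.n_gap
            m, M = ev.n_present_in_background, ev.n_background
            present = k + m
            # P(X >= k) by direct summation over the hypergeometric pmf
            oracle = sum(
                math.comb(present, i) * math.comb(K + M - present, K - i)
                for i in range(k, min(K, present) + 1)
            ) / math.comb(K + M, K)
            assert ev.p_value == pytest.approx(oracle)

    def test_p_decreases_as_gap_presence_grows(self):
        genomes = [f"g{i}" for i in range(10)]
        gap = PathwayGap("P", "R", frozenset(genomes[:5]),
                         frozenset(genomes[5:]))
        ps = []
        for k in range(6):
            row = [i < k for i in range(5)] + [False] * 5
            matrix = pd.DataFrame([row], index=["fam"], columns=genomes)
            (ev,) = profile_match(gap, matrix)
            ps.append(ev.p_value)
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_exact_match_p_is_margin_minimum(self):
        genomes = [f"g{i}" for i in range(8)]
        gap = PathwayGap("P", "R", frozenset(genomes[:3]),
                         frozenset(genomes[3:]))
        exact_row = [True] * 3 + [False] * 5
        ps = []
        for shift in range(4):
            row = exact_row[shift:] + exact_row[:shift]
            matrix = pd.DataFrame([row], index=["fam"], columns=genomes)
            (ev,) = profile_match(gap, matrix)
            ps.append((ev.exact_match, ev.p_value))
        assert ps[0][0]
        assert ps[0][1] == min(p for _, p in ps)

    def test_empty_gap_rejected(self):
        matrix = pd.DataFrame([[True]], index=["f"], columns=["g1"])
        gap = PathwayGap("P", "R", frozenset(), frozenset({"g1"}))
        with pytest.raises(ValueError):
            profile_match(gap, matrix)


class TestColocalization:
    def _genome(self, positions):
        seq = "MKTAYIAKQRMKTAYIAKQR"
        layout = {"c1": [(f"x{i}", seq) for i in range(max(positions.values()) + 1)]}
        g = build_genome("G", layout)
        return g, {name: f"x{pos}" for name, pos in positions.items()}

    @pytest.mark.parametrize(
        "cand_pos,max_interv,expected", [(1, 0, True), (2, 0, False),
                                         (4, 3, True), (5, 3, False)]
    )
    def test_rank_distance_boundary(self, cand_pos, max_interv, expected):
        genome, ids = self._genome({"anchor": 0, "cand": cand_pos})
        evidence = colocalization(
            [("G", ids["cand"])], {"G": {ids["anchor"]}}, {"G": genome},
            max_intervening=max_interv,
        )
        assert bool(evidence) is expected
        if expected:
            assert evidence[0].min_intervening_genes == cand_pos - 1

    def test_different_contig_never_colocalizes(self):
        seq = "MKTAYIAKQRMKTAYIAKQR"
        genome = build_genome(
            "G", {"c1": [("anchor", seq)], "c2": [("cand", seq)]}
        )
        assert colocalization(
            [("G", "cand")], {"G": {"anchor"}}, {"G": genome}
        ) == []

    def test_nearest_anchor_reported_first(self):
        genome, ids = self._genome({"a_far": 0, "cand": 3, "a_near": 4})
        (ev,) = colocalization(
            [("G", ids["cand"])],
            {"G": {ids["a_far"], ids["a_near"]}},
            {"G": genome},
        )
        assert ev.anchor_genes[0] == ids["a_near"]
        assert ev.min_intervening_genes == 0


class TestFusionScan:
    def _genome_with_domains(self, domains):
        seq = "MKTAYIAKQR" * 8
        return build_genome(
            "G", {"c1": [("p1", seq)]},
            domains=[DomainHit("p1", acc, s, e, 40.0)
                     for acc, s, e in domains],
        )

    def test_candidate_then_role_domain_detected(self):
        g = self._genome_with_domains(
            [("PF08282", 1, 30), ("PF03061", 40, 75)]
        )
        (ev,) = fusion_scan({"PF08282"}, {"PF03061"}, [g])
        assert ev.domain_pair == ("PF08282", "PF03061")
        assert ev.architecture == "PF08282-PF03061"

    def test_order_swapped_still_detected_with_different_architecture(self):
        g = self._genome_with_domains(
            [("PF03061", 1, 30), ("PF08282", 40, 75)]
        )
        (ev,) = fusion_scan({"PF08282"}, {"PF03061"}, [g])
        assert ev.architecture == "PF03061-PF08282"

    def test_single_domain_protein_yields_nothing(self):
        g = self._genome_with_domains([("PF08282", 1, 30)])
        assert fusion_scan({"PF08282"}, {"PF03061"}, [g]) == []


class TestRanking:
    def _gap(self):
        return PathwayGap("P", "R", frozenset({"g1", "g2"}),
                          frozenset({"g3"}))

    def _profile(self, fam, p):
        return ProfileEvidence(fam, 2, 2, 0, 1, True, p)

    def test_colocalized_candidate_outranks_equal_profile(self):
        gap = self._gap()
        profiles = [self._profile("famA", 0.01), self._profile("famB", 0.01)]
        from quinrec.displacement import ColocalizationEvidence

        colocs = {
            "famB": [ColocalizationEvidence("g1", "x", ("a",), 0),
                     ColocalizationEvidence("g2", "y", ("a",), 0)]
        }
        ranked = rank_candidates(gap, profiles, colocs, {})
        assert [c.candidate_family for c in ranked] == ["famB", "famA"]
        assert [c.rank for c in ranked] == [1, 2]

    def test_single_candidate_gets_rank_one(self):
        (c,) = rank_candidates(self._gap(), [self._profile("famA", 0.5)])
        assert c.rank == 1

    def test_ranking_invariant_under_profile_permutation(self):
        gap = self._gap()
        profiles = [
            self._profile("famA", 0.05),
            self._profile("famB", 0.01),
            self._profile("famC", 0.20),
        ]
        forward = rank_candidates(gap, profiles)
        backward = rank_candidates(gap, profiles[::-1])
        assert [c.candidate_family for c in forward] == [
            c.candidate_family for c in backward
        ]

    def test_ties_rank_densely_with_lexicographic_order(self):
        gap = self._gap()
        profiles = [self._profile("famB", 0.01), self._profile("famA", 0.01)]
        ranked = rank_candidates(gap, profiles)
        assert [(c.candidate_family, c.rank) for c in ranked] == [
            ("famA", 1), ("famB", 1)
        ]


class TestCoOccurrence:
    def test_perfect_triplet_passes(self):
        genomes = ["g1", "g2", "g3", "g4"]
        rows = {f: [True, True, False, False] for f in ("mqnP", "mqnL", "mqnM")}
        matrix = pd.DataFrame(rows).T
        matrix.columns = genomes
        ok, counts = co_occurrence_check(
            ["mqnP", "mqnL", "mqnM"], ["g1", "g2"], matrix
        )
        assert ok and counts["violations"] == 0

    def test_one_missing_member_counts_one_violation(self):
        genomes = ["g1", "g2", "g3"]
        matrix = pd.DataFrame(
            {"g1": [True, True], "g2": [True, False], "g3": [False, False]},
            index=["fA", "fB"],
        )
        ok, counts = co_occurrence_check(["fA", "fB"], ["g1", "g2"], matrix)
        assert not ok
        assert counts == {
            "missing_in_pathway_genomes": 1,
            "present_in_other_genomes": 0,
            "violations": 1,
        }

    @pytest.mark.parametrize("seed", range(3))
    def test_random_matrix_matches_set_comparison_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genomes = [f"g{i}" for i in range(8)]
        fams = [f"f{i}" for i in range(4)]
        matrix = pd.DataFrame(
            rng.random((4, 8)) < 0.5, index=fams, columns=genomes
        )
        positive = [g for g in genomes if rng.random() < 0.4]
        ok, counts = co_occurrence_check(fams, positive, matrix)
        expected_ok = all(
            set(matrix.columns[matrix.loc[f]]) == set(positive) for f in fams
        )
        assert ok == expected_ok
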