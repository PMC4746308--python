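"""Alignment, bidirectional best hits, and family construction."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from conftest import AA, build_genome, mutate, random_protein
from quinrec.orthology import (
    KA_K,
    KA_LAMBDA,
    OrthologPair,
    OrthologyParams,
    align_pair,
    best_hits,
    build_families,
    call_bbh,
    presence_matrix,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")
LENIENT = OrthologyParams(min_identity=0.0, min_bits=0.0, min_coverage=0.0,
                          prefilter_kmer=0)


def sw_affine_oracle(a: str, b: str, open_=11.0, ext=1.0) -> float:
    """Exhaustive Gotoh local-alignment DP, cell by cell (gap of length L
    costs open + (L-1)*extend, matching the implementation's convention)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = float(BLOSUM62[a[i - 1], b[j - 1]])
            Ix[i][j] = max(M[i - 1][j] - open_, Ix[i - 1][j] - ext)
            Iy[i][j] = max(M[i][j - 1] - open_, Iy[i][j - 1] - ext)
            M[i][j] = max(
                0.0,
                s + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]),
            )
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return best


class TestAlignPair:
    def test_self_alignment_identity_and_score(self):
        seq = "MKTAYIAKQR"
        res = align_pair(seq, seq)
        assert res.identity == 1.0
        assert res.score == sum(float(BLOSUM62[c, c]) for c in seq)
        assert res.aligned_columns == len(seq)

    def test_all_negative_substitutions_give_empty_alignment(self):
        res = align_pair("WWWW", "PPPP")  # W/P scores -4
        assert res.score == 0.0
        assert res.identity == 0.0
        assert res.aligned_columns == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "MKT")

    def test_score_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = random_protein(rng, int(rng.integers(5, 30)))
            b = random_protein(rng, int(rng.integers(5, 30)))
            assert align_pair(a, b, LENIENT).score == align_pair(b, a, LENIENT).score

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_dp_oracle_on_short_peptides(self, seed):
        rng = np.random.default_rng(seed)
        a = random_protein(rng, int(rng.integers(4, 13)))
        b = random_protein(rng, int(rng.integers(4, 13)))
        assert align_pair(a, b, LENIENT).score == pytest.approx(
            sw_affine_oracle(a, b)
        )


def _two_genomes(rng, n_genes=5, mut=0.15, length=90):
    fams = [random_protein(rng, length) for _ in range(n_genes)]
    ga = build_genome("A", {"c1": [(f"a{i}", s) for i, s in enumerate(fams)]})
    gb = build_genome(
        "B", {"c1": [(f"b{i}", mutate(rng, s, mut)) for i, s in enumerate(fams)]}
    )
    return ga, gb


class TestBestHitsAndBBH:
    def test_identical_genomes_map_every_gene_to_its_copy(self):
        rng = np.random.default_rng(1)
        seqs = [(f"g{i}", random_protein(rng, 80)) for i in range(4)]
        ga = build_genome("A", {"c1": seqs})
        gb = build_genome("B", {"c1": seqs})
        assert best_hits(ga, gb) == {gid: gid for gid, _ in seqs}

    def test_subthreshold_homolog_excluded_at_defaults(self):
        # ~85% of positions mutated: the surviving local match is a short
        # weak window that fails the bit-score / coverage thresholds
        rng = np.random.default_rng(5)
        anc = random_protein(rng, 100)
        far = mutate(rng, anc, 0.85)
        near = mutate(rng, anc, 0.3)
        ga = build_genome("A", {"c1": [("q", anc)]})
        gb = build_genome("B", {"c1": [("far", far)]})
        gb2 = build_genome("B2", {"c1": [("near", near)]})
        assert best_hits(ga, gb) == {}
        assert best_hits(ga, gb2) == {"q": "near"}

    def test_best_hits_equal_brute_force_argmax(self):
        rng = np.random.default_rng(7)
        ga, gb = _two_genomes(rng)
        params = OrthologyParams(prefilter_kmer=0)
        got = best_hits(ga, gb, params)

        expected = {}
        for ga_id, pa in sorted(ga.proteins.items()):
            best = None
            for gb_id, pb in sorted(gb.proteins.items()):
                res = align_pair(pa.sequence, pb.sequence, LENIENT)
                bits = (KA_LAMBDA * res.score - math.log(KA_K)) / math.log(2)
                if (
                    res.identity < 0.20
                    or bits < 25.0
                    or res.aligned_columns
                    < 0.5 * max(len(pa.sequence), len(pb.sequence))
                ):
                    continue
                if best is None or res.score > best[0]:
                    best = (res.score, gb_id)
            if best:
                expected[ga_id] = best[1]
        assert got == expected

    def test_reciprocity_required(self):
        rng = np.random.default_rng(11)
        s = random_protein(rng, 80)
        ga = build_genome(
            "A", {"c1": [("a_exact", s), ("a_mut", mutate(rng, s, 0.1))]}
        )
        gb = build_genome("B", {"c1": [("b", s)]})
        pairs = call_bbh(ga, gb)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a_exact", "b")]

    def test_bbh_symmetric_under_genome_swap(self):
        rng = np.random.default_rng(13)
        ga, gb = _two_genomes(rng, n_genes=4)
        ab = {(p.gene_a, p.gene_b) for p in call_bbh(ga, gb)}
        ba = {(p.gene_b, p.gene_a) for p in call_bbh(gb, ga)}
        assert ab == ba and ab

    def test_identical_genomes_context_similarity_is_one(self):
        rng = np.random.default_rng(17)
        seqs = [(f"g{i}", random_protein(rng, 80)) for i in range(4)]
        pairs = call_bbh(
            build_genome("A", {"c1": seqs}), build_genome("B", {"c1": seqs})
        )
        assert len(pairs) == 4
        assert all(p.context_similarity == 1.0 for p in pairs)


def _fake_pair(ga, a, gb, b, score=300.0):
    return OrthologPair(ga, a, gb, b, score, 0.9, 1.0)


class TestFamilies:
    def test_conserved_gene_in_three_genomes_forms_one_family(self):
        rng = np.random.default_rng(19)
        s = random_protein(rng, 90)
        genomes = [
            build_genome(g, {"c1": [(f"{g}_x", mutate(rng, s, 0.1))]})
            for g in ("A", "B", "C")
        ]
        catalog = build_families(genomes)
        assert len(catalog) == 1
        (members,) = catalog.values()
        assert members == {("A", "A_x"), ("B", "B_x"), ("C", "C_x")}

    def test_unrelated_sets_stay_disjoint_and_singletons_survive(self):
        rng = np.random.default_rng(23)
        s1, s2 = random_protein(rng, 90), random_protein(rng, 90)
        ga = build_genome("A", {"c1": [("a1", s1), ("a2", s2)]})
        gb = build_genome("B", {"c1": [("b1", mutate(rng, s1, 0.1))]})
        catalog = build_families([ga, gb])
        sizes = sorted(len(m) for m in catalog.values())
        assert sizes == [1, 2]

    def test_components_match_union_find_oracle_on_random_graph(self):
        rng = np.random.default_rng(29)
        genomes = [
            build_genome(g, {"c1": [(f"{g}_{i}", "MKTAYIAKQRMKTAYIAKQR")
                                    for i in range(6)]})
            for g in ("A", "B", "C")
        ]
        nodes = [(g.genome_id, gid) for g in genomes for gid in g.gene_ids]
        pairs = []
        for _ in range(10):
            (ga, a), (gb, b) = (
                nodes[int(rng.integers(len(nodes)))] for _ in range(2)
            )
            if ga != gb:
                pairs.append(_fake_pair(ga, a, gb, b))
        catalog = build_families(genomes, pairs=pairs)

        parent = {n: n for n in nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for p in pairs:
            ra, rb = find((p.genome_a, p.gene_a)), find((p.genome_b, p.gene_b))
            parent[ra] = rb
        oracle = {}
        for n in nodes:
            oracle.setdefault(find(n), set()).add(n)
        assert sorted(catalog.values(), key=sorted) == sorted(
            oracle.values(), key=sorted
        )

    def test_families_partition_gene_universe(self):
        rng = np.random.default_rng(31)
        ga, gb = _two_genomes(rng, n_genes=4)
        catalog = build_families([ga, gb])
        all_members = [m for ms in catalog.values() for m in ms]
        assert len(all_members) == len(set(all_members)) == 8

    def test_presence_matrix_matches_membership_oracle(self):
        rng = np.random.default_rng(37)
        ga, gb = _two_genomes(rng, n_genes=4)
        catalog = build_families([ga, gb])
        matrix = presence_matrix(catalog, [ga, gb])
        for fam, members in catalog.items():
            for genome in ("A", "B"):
                assert matrix.loc[fam, genome] == any(
                    gn == genome for gn, _ in members
                )

    def test_family_recovery_on_synthetic_cohort(self):
        """Rand index >= 0.95 vs the generator's true families at default
        parameters and <= 0.3 substitutions/site divergence."""
        from quinrec import synthgen
        from quinrec.orthology import family_table

        genomes, manifest = synthgen.simulate(synthgen.cohort_config(41))
        catalog = build_families(genomes)
        inferred = {}
        for fam, members in catalog.items():
            for member in members:
                inferred[member] = fam
        truth = {
            (g, gid): fam
            for g, genes in manifest.families.items()
            for gid, fam in genes.items()
        }
        keys = sorted(truth)
        agree = total = 0
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                same_true = truth[keys[i]] == truth[keys[j]]
                same_inf = inferred[keys[i]] == inferred[keys[j]]
                agree += same_true == same_inf
                total += 1
        assert agree / total >= 0.95
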