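"""Ortholog detection by bidirectional best hits with genomic-context support.

The operational ortholog definition is the classic one for microbial
comparative genomics: two genes in two genomes are orthologs when each is the
other's best-scoring hit (BBH) and their chromosomal neighborhoods look alike.
Alignment is exact local Smith-Waterman under BLOSUM62 with affine gaps
(Bio.Align.PairwiseAligner); spurious hits are rejected by a Karlin-Altschul
bit-score surrogate for a BLAST E-value cutoff plus a minimum percent
identity (default 20%, computed over all aligned columns including gaps).

Families are connected components of the BBH graph across all genomes;
the family x genome boolean presence matrix built from them is the substrate
for phylogenetic profiling downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import AnnotatedGenome

# Karlin-Altschul parameters for gapped BLOSUM62 (11/1), standard BLAST values
KA_LAMBDA = 0.267
KA_K = 0.041
LN2 = math.log(2.0)


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    identity: float
    aligned_columns: int

    @property
    def bits(self) -> float:
        """Normalized bit score (Karlin-Altschul)."""
        return (KA_LAMBDA * self.score - math.log(KA_K)) / LN2


@dataclass(frozen=True)
class OrthologPair:
    genome_a: str
    gene_a: str
    genome_b: str
    gene_b: str
    score: float
    identity: float
    context_similarity: float
    context_pass: bool = True


@dataclass(frozen=True)
class OrthologyParams:
    """Thresholds for hit acceptance and context scoring.

    ``min_bits`` is the surrogate for a BLAST E-value cutoff: with the
    gapped-BLOSUM62 Karlin-Altschul parameters, 25 bits passes genuine
    length-100 matches at 20-25% identity while rejecting random-sequence
    scores. ``min_context_jaccard`` is advisory (0.0) by default because
    "similar genomic context" is never quantified; failing pairs are flagged,
    not dropped.
    """

    min_identity: float = 0.20
    min_bits: float = 25.0
    min_coverage: float = 0.50    # aligned columns / longer sequence length
    strong_bits: float = 50.0     # edges below this need triangle support
    context_window: int = 5
    min_context_jaccard: float = 0.0
    gap_open: float = 11.0
    gap_extend: float = 1.0
    prefilter_kmer: int = 4        # 0 disables the shared-k-mer prescreen
    prefilter_min_shared: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0, 1]")


def _make_aligner(params: OrthologyParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_pair(
    seq_a: str, seq_b: str, params: OrthologyParams | None = None
) -> AlignmentResult:
    """Optimal local alignment of two protein sequences.

    Returns the Smith-Waterman score, the identity fraction over aligned
    columns (gap columns included in the denominator), and the column count.
    A pair with no positive-scoring alignment yields score 0 and identity 0.
    """
    if not seq_a or not seq_b:
        raise ValueError("align_pair: empty sequence")
    params = params or OrthologyParams()
    aligner = _make_aligner(params)
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return AlignmentResult(0.0, 0.0, 0)
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    columns = aln.length
    return AlignmentResult(float(score), counts.identities / columns, columns)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class _Prefilter:
    """Shared-k-mer prescreen: skip Smith-Waterman for pairs sharing no seed."""

    def __init__(self, genome: AnnotatedGenome, k: int):
        self.k = k
        self.kmer_sets = (
            {gid: _kmers(p.sequence, k) for gid, p in genome.proteins.items()}
            if k > 0
            else {}
        )

    def shared(self, gid: str, other: set[str]) -> int:
        return len(self.kmer_sets[gid] & other)


def _passes(
    result: AlignmentResult, len_a: int, len_b: int, params: OrthologyParams
) -> bool:
    # short high-scoring local windows between unrelated proteins are the
    # main false-positive mode; mutual coverage (longer-sequence denominator)
    # rejects them - including partial matches of multi-domain proteins
    # against single-domain ones - while full-length homologs at low
    # identity still pass
    return (
        result.aligned_columns > 0
        and result.identity >= params.min_identity
        and result.bits >= params.min_bits
        and result.aligned_columns >= params.min_coverage * max(len_a, len_b)
    )


def best_hits(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    params: OrthologyParams | None = None,
) -> dict[str, str]:
    """Best passing hit in ``genome_b`` for each gene of ``genome_a``.

    Ties on score break to the lexicographically smallest target id so runs
    are bit-reproducible. Genes with no passing hit are absent from the map.
    """
    params = params or OrthologyParams()
    if not genome_a.genes or not genome_b.genes:
        raise ValueError("best_hits: empty genome")
    k = params.prefilter_kmer
    pf_b = _Prefilter(genome_b, k)
    out: dict[str, str] = {}
    for gid_a in sorted(genome_a.proteins):
        seq_a = genome_a.proteins[gid_a].sequence
        kmers_a = _kmers(seq_a, k) if k > 0 else set()
        best: tuple[float, str] | None = None
        for gid_b in sorted(genome_b.proteins):
            if k > 0 and pf_b.shared(gid_b, kmers_a) < params.prefilter_min_shared:
                continue
            seq_b = genome_b.proteins[gid_b].sequence
            res = align_pair(seq_a, seq_b, params)
            if not _passes(res, len(seq_a), len(seq_b), params):
                continue
            if best is None or res.score > best[0]:
                best = (res.score, gid_b)
        if best is not None:
            out[gid_a] = best[1]
    return out


def _context_jaccard(
    genome_a: AnnotatedGenome,
    gene_a: str,
    genome_b: AnnotatedGenome,
    gene_b: str,
    ab_hits: Mapping[str, str],
    window: int,
) -> float:
    """Jaccard of b-side neighbor sets: actual neighbors of ``gene_b`` vs the
    best-hit images of ``gene_a``'s neighbors."""
    mapped = {
        ab_hits[n.gene_id]
        for n in genome_a.neighbors(gene_a, window)
        if n.gene_id in ab_hits
    }
    actual = {n.gene_id for n in genome_b.neighbors(gene_b, window)}
    if not mapped and not actual:
        return 1.0
    union = mapped | actual
    return len(mapped & actual) / len(union)


def call_bbh(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    params: OrthologyParams | None = None,
) -> list[OrthologPair]:
    """Reciprocal best hits between two genomes, with context similarity.

    Pairs whose context Jaccard falls below ``min_context_jaccard`` are
    flagged (``context_pass=False``), never silently dropped.
    """
    params = params or OrthologyParams()
    ab = best_hits(genome_a, genome_b, params)
    ba = best_hits(genome_b, genome_a, params)
    pairs: list[OrthologPair] = []
    for gid_a in sorted(ab):
        gid_b = ab[gid_a]
        if ba.get(gid_b) != gid_a:
            continue
        res = align_pair(
            genome_a.proteins[gid_a].sequence, genome_b.proteins[gid_b].sequence,
            params,
        )
        ctx = _context_jaccard(
            genome_a, gid_a, genome_b, gid_b, ab, params.context_window
        )
        pairs.append(
            OrthologPair(
                genome_a.genome_id, gid_a, genome_b.genome_id, gid_b,
                res.score, res.identity, ctx,
                context_pass=ctx >= params.min_context_jaccard,
            )
        )
    return pairs


def build_families(
    genomes: Sequence[AnnotatedGenome],
    params: OrthologyParams | None = None,
    pairs: Iterable[OrthologPair] | None = None,
) -> dict[str, set[tuple[str, str]]]:
    """Gene families as connected components of the cross-genome BBH graph.

    Single-linkage over BBH edges; genes with no ortholog form singleton
    families. Family ids ``F00001...`` are assigned in sort order of each
    component's smallest (genome_id, gene_id) member, making the catalog
    deterministic. Context-flagged pairs still contribute edges when
    ``min_context_jaccard`` is 0 (advisory); otherwise only passing pairs do.

    Weak edges (below ``strong_bits``, i.e. in the twilight zone where
    random local similarities live) must be triangle-supported - some third
    gene strongly BBH-paired with both endpoints - before they can merge
    components.  Orthology within a family is transitive across genomes, so
    genuine weak edges have such witnesses; spurious similarities do not
    (even recurrent ones, since their supporting edges are weak too).
    """
    if not genomes:
        raise ValueError("build_families: need at least one genome")
    params = params or OrthologyParams()
    if pairs is None:
        pairs = [
            p
            for ga, gb in combinations(genomes, 2)
            for p in call_bbh(ga, gb, params)
        ]
    graph = nx.Graph()
    for genome in genomes:
        for gid in genome.gene_ids:
            graph.add_node((genome.genome_id, gid))
    for p in pairs:
        if p.context_pass:
            bits = (KA_LAMBDA * p.score - math.log(KA_K)) / LN2
            graph.add_edge(
                (p.genome_a, p.gene_a), (p.genome_b, p.gene_b), bits=bits
            )
    strong_adj: dict = {}
    for u, v, bits in graph.edges(data="bits"):
        if bits >= params.strong_bits:
            strong_adj.setdefault(u, set()).add(v)
            strong_adj.setdefault(v, set()).add(u)
    unsupported = [
        (u, v)
        for u, v, bits in graph.edges(data="bits")
        if bits < params.strong_bits
        and not (strong_adj.get(u, set()) & strong_adj.get(v, set()) - {u, v})
    ]
    graph.remove_edges_from(unsupported)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    return {
        f"F{i:05d}": set(comp) for i, comp in enumerate(components, start=1)
    }


def presence_matrix(
    catalog: Mapping[str, set[tuple[str, str]]],
    genomes: Sequence[AnnotatedGenome],
) -> pd.DataFrame:
    """Boolean family x genome matrix: entry true iff the family has a member
    in the genome."""
    genome_ids = [g.genome_id for g in genomes]
    data = {
        fam: [any(member_gn == gn for member_gn, _ in members)
              for gn in genome_ids]
        for fam, members in sorted(catalog.items())
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=genome_ids)
    return df.astype(bool)


def pairs_table(pairs: Iterable[OrthologPair]) -> pd.DataFrame:
    rows = [
        (p.genome_a, p.gene_a, p.genome_b, p.gene_b, p.score, p.identity,
         p.context_similarity, p.context_pass)
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=["genome_a", "gene_a", "genome_b", "gene_b", "score",
                 "identity", "context_jaccard", "context_pass"],
    )


def family_table(catalog: Mapping[str, set[tuple[str, str]]]) -> pd.DataFrame:
    rows = [
        (fam, gn, gid)
        for fam, members in sorted(catalog.items())
        for gn, gid in sorted(members)
    ]
    return pd.DataFrame(rows, columns=["family_id", "genome_id", "gene_id"])
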