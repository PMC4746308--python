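"""Distance-based phylogenetics for homolog-group separation tests.

The claims this module supports are topological: do the UbiA-like,
MqnP-like and MenA-like proteins each form their own monophyletic branch
(distinct substrate specificities), and do the UbiE/MenG-like methyl-
transferases fail to separate (one shared function)?  Neighbor-joining on
Poisson-corrected distances answers such questions; likelihood inference
would add branch-length rigor the questions do not need.

A minimal deterministic progressive aligner is included (guide tree from
k-mer distances, profile-profile Needleman-Wunsch merges); NJ and midpoint
rooting are delegated to scikit-bio.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_GAP = "-"


@dataclass(frozen=True)
class MultipleAlignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{r}\n" for i, r in zip(self.ids, self.rows))

    @classmethod
    def from_fasta(cls, text: str) -> "MultipleAlignment":
        ids, rows, cur = [], [], []
        for line in text.splitlines():
            if line.startswith(">"):
                if cur:
                    rows.append("".join(cur))
                    cur = []
                ids.append(line[1:].split()[0])
            elif line.strip():
                cur.append(line.strip())
        if cur:
            rows.append("".join(cur))
        return cls(tuple(ids), tuple(rows))


def _sub_score(a: str, b: str) -> float:
    try:
        return float(_BLOSUM[a, b])
    except (KeyError, IndexError):
        return 0.0


# precomputed substitution table over the indexed alphabet
_IDX = {c: i for i, c in enumerate(_ALPHABET)}
_SUBS = np.array(
    [[_sub_score(a, b) for b in _ALPHABET] for a in _ALPHABET], dtype=float
)


def _profile(rows: Sequence[str]) -> np.ndarray:
    """Columns x (alphabet + gap) frequency profile."""
    n_sym = len(_ALPHABET) + 1
    prof = np.zeros((len(rows[0]), n_sym))
    for row in rows:
        for j, c in enumerate(row):
            prof[j, _IDX.get(c, n_sym - 1)] += 1
    return prof / len(rows)


def _profile_scores(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Pairwise column-score matrix between two profiles (gap symbol scores 0)."""
    ra, rb = pa[:, :-1], pb[:, :-1]  # drop gap frequency; gap-vs-X contributes 0
    return ra @ _SUBS @ rb.T


def _merge(
    rows_a: list[str], rows_b: list[str], gap_open: float, gap_extend: float
) -> tuple[list[str], list[str]]:
    """Profile-profile global alignment with affine-ish linear penalties."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    S = _profile_scores(pa, pb)
    n, m = S.shape
    # linear-gap DP with open penalty on gap start (affine, single state kept
    # simple: penalty = open for first, extend after; tracked via move matrix)
    NEG = -1e12
    M = np.full((n + 1, m + 1), NEG)
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up(a-gap-b), 2 left
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        M[i, 0] = -gap_open - (i - 1) * gap_extend
        move[i, 0] = 1
    for j in range(1, m + 1):
        M[0, j] = -gap_open - (j - 1) * gap_extend
        move[0, j] = 2
    for i in range(1, n + 1):
        Si = S[i - 1]
        for j in range(1, m + 1):
            diag = M[i - 1, j - 1] + Si[j - 1]
            up = M[i - 1, j] - (gap_extend if move[i - 1, j] == 1 else gap_open)
            left = M[i, j - 1] - (gap_extend if move[i, j - 1] == 2 else gap_open)
            best = diag
            mv = 0
            if up > best:
                best, mv = up, 1
            if left > best:
                best, mv = left, 2
            M[i, j] = best
            move[i, j] = mv
    # traceback
    out_a: list[list[str]] = [[] for _ in rows_a]
    out_b: list[list[str]] = [[] for _ in rows_b]
    i, j = n, m
    while i > 0 or j > 0:
        mv = move[i, j]
        if mv == 0 and i > 0 and j > 0:
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i - 1])
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j - 1])
            i, j = i - 1, j - 1
        elif mv == 1 and i > 0:
            for k, r in enumerate(rows_a):
                out_a[k].append(r[i - 1])
            for k in range(len(rows_b)):
                out_b[k].append(_GAP)
            i -= 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append(_GAP)
            for k, r in enumerate(rows_b):
                out_b[k].append(r[j - 1])
            j -= 1
    return (
        ["".join(reversed(r)) for r in out_a],
        ["".join(reversed(r)) for r in out_b],
    )


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(max(len(a) - k + 1, 1))}
    kb = {b[i : i + k] for i in range(max(len(b) - k + 1, 1))}
    union = ka | kb
    return 1.0 - (len(ka & kb) / len(union) if union else 0.0)


def progressive_align(
    sequences: Mapping[str, str],
    gap_open: float = 15.0,
    gap_extend: float = 0.5,
) -> MultipleAlignment:
    """Deterministic progressive multiple alignment.

    Guide tree: NJ on k-mer (k=3) distances (for two sequences the join is
    trivial); merges: profile-profile Needleman-Wunsch with the classic
    ClustalX-era penalties (open 15, extend 0.5) over BLOSUM62.
    """
    ids = sorted(sequences)
    if len(ids) < 2:
        raise ValueError("progressive_align: need >= 2 sequences")
    groups: dict[str, tuple[list[str], list[str]]] = {
        i: ([i], [sequences[i]]) for i in ids
    }
    order = _merge_order(ids, sequences)
    for left, right, merged in order:
        ids_a, rows_a = groups.pop(left)
        ids_b, rows_b = groups.pop(right)
        new_a, new_b = _merge(rows_a, rows_b, gap_open, gap_extend)
        groups[merged] = (ids_a + ids_b, new_a + new_b)
    (final_ids, final_rows), = groups.values()
    # restore canonical id order
    paired = sorted(zip(final_ids, final_rows))
    return MultipleAlignment(
        tuple(i for i, _ in paired), tuple(r for _, r in paired)
    )


def _merge_order(
    ids: list[str], sequences: Mapping[str, str]
) -> list[tuple[str, str, str]]:
    """Postorder merge schedule from the k-mer guide tree."""
    if len(ids) == 2:
        return [(ids[0], ids[1], "root")]
    data = [[_kmer_distance(sequences[a], sequences[b]) for b in ids] for a in ids]
    tree = nj(DistanceMatrix(np.array(data), ids))
    schedule: list[tuple[str, str, str]] = []
    counter = [0]

    def walk(node: TreeNode) -> str:
        if node.is_tip():
            return str(node.name)
        names = [walk(c) for c in node.children]
        current = names[0]
        for other in names[1:]:
            counter[0] += 1
            merged = f"_m{counter[0]}"
            schedule.append((current, other, merged))
            current = merged
        return current

    walk(tree)
    return schedule


# ---------------------------------------------------------------------------
# distances, trees, monophyly

def distance_matrix(
    alignment: MultipleAlignment, model: str = "poisson"
) -> DistanceMatrix:
    """Pairwise distances with pairwise gap deletion.

    ``p_distance``: mismatches / comparable columns. ``poisson``:
    -ln(1 - p), with p capped just below 1 for saturated pairs.
    """
    if model not in {"p_distance", "poisson"}:
        raise ValueError(f"unknown distance model {model!r}")
    n = len(alignment.ids)
    mat = np.zeros((n, n))
    rows = alignment.rows
    for i in range(n):
        for j in range(i + 1, n):
            comparable = mismatch = 0
            for a, b in zip(rows[i], rows[j]):
                if a == _GAP or b == _GAP:
                    continue
                comparable += 1
                if a != b:
                    mismatch += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {alignment.ids[i]!r} "
                    f"and {alignment.ids[j]!r}"
                )
            p = mismatch / comparable
            if model == "poisson":
                d = -math.log(max(1.0 - p, 1e-6))
            else:
                d = p
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, list(alignment.ids))


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted; negative branch lengths clamped)."""
    if dm.shape[0] < 3:
        raise ValueError("nj_tree: need >= 3 taxa")
    return nj(dm)


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    tips = list(tree.tips())
    if len(tips) == 2:  # degenerate: split the single path in half
        half = sum(t.length or 0.0 for t in tips) / 2.0
        a, b = (t.name for t in tips)
        return TreeNode.read([f"({a}:{half},{b}:{half});"])
    return tree.copy().root_at_midpoint()


def is_monophyletic(rooted_tree: TreeNode, leaf_set: Iterable[str]) -> bool:
    """True iff some clade's tip set equals ``leaf_set`` exactly."""
    query = set(leaf_set)
    if not query:
        raise ValueError("is_monophyletic: empty leaf set")
    tips = {t.name for t in rooted_tree.tips()}
    unknown = query - tips
    if unknown:
        raise ValueError(f"unknown leaves {sorted(unknown)}")
    if query == tips:
        return True
    for node in rooted_tree.traverse(include_self=True):
        clade = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        if clade == query:
            return True
    return False


def separation_report(
    rooted_tree: TreeNode, labeling: Mapping[str, str]
) -> dict[str, object]:
    """Per-group monophyly verdicts, plus flagged group pairs whose *union*
    is a clade although neither group alone is (the "mixed branch" outcome).
    """
    tips = {t.name for t in rooted_tree.tips()}
    unlabeled = tips - labeling.keys()
    if unlabeled:
        raise ValueError(f"labeling not total: missing {sorted(unlabeled)}")
    groups: dict[str, set[str]] = {}
    for leaf, lab in labeling.items():
        if leaf in tips:
            groups.setdefault(lab, set()).add(leaf)
    verdicts = {
        lab: is_monophyletic(rooted_tree, members)
        for lab, members in sorted(groups.items())
    }
    mixed_pairs = []
    labs = sorted(groups)
    for i, la in enumerate(labs):
        for lb in labs[i + 1 :]:
            if verdicts[la] and verdicts[lb]:
                continue
            if is_monophyletic(rooted_tree, groups[la] | groups[lb]):
                mixed_pairs.append((la, lb))
    return {"monophyletic": verdicts, "mixed_pairs": mixed_pairs}


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path))


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path))
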