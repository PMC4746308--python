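"""Reusable benchmark harnesses: printed-table arithmetic, planted-signal
recovery on synthetic cohorts, and determinism checks.

These drive both the test suite and the reproduction script.  Every
benchmark generates its own inputs from a seed, runs the regular package
code paths, and measures the outcome against the generator's truth
manifest.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import shutil
import tempfile
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import pathway_recon as pr
from . import phylo, sdp, synthgen
from .codistribution import CodistCall, agreement_stats
from .pipeline import RunConfig, run_pipeline

# ---------------------------------------------------------------------------
# printed-table arithmetic


def codistribution_stats_from_counts(counts: Mapping[str, int]) -> dict:
    """Agreement statistics recomputed from per-category genome counts.

    Builds one :class:`CodistCall` per genome and runs the regular
    statistics path, so the percentages are produced by the package's own
    arithmetic, not copied in.
    """
    calls = [
        CodistCall(f"g{i:03d}", category, (), ())
        for i, category in enumerate(
            itertools.chain.from_iterable(
                [cat] * n for cat, n in sorted(counts.items())
            )
        )
    ]
    return agreement_stats(calls)


def enumerate_quinone_patterns() -> set[frozenset]:
    """All distinct quinone-synthesis patterns over consistent inputs.

    Enumerates every combination of Ubi completeness, Men/Mqn DMK
    capability and menG presence that the inference rules accept, and
    collects the resulting patterns.
    """

    def call(pid: str, status: str, missing: tuple[str, ...]) -> pr.PathwayCall:
        present = ("x",) if status != pr.ABSENT else ()
        return pr.PathwayCall("g", pid, status, present, missing)

    men_variants = {
        "complete": call("Men", pr.COMPLETE, ()),
        "meng_only_missing": call("Men", pr.INCOMPLETE, (pr.MENG_ROLE,)),
        "broken": call("Men", pr.INCOMPLETE, ("MenD",)),
        "absent": call("Men", pr.ABSENT, ("MenF", "MenD")),
    }
    mqn_variants = {
        "complete": call("Mqn_core", pr.COMPLETE, ()),
        "broken": call("Mqn_core", pr.INCOMPLETE, ("MqnC",)),
        "absent": call("Mqn_core", pr.ABSENT, ("MqnA",)),
    }
    ubi_variants = {
        "complete": call("Ubi", pr.COMPLETE, ()),
        "absent": call("Ubi", pr.ABSENT, ("UbiC",)),
    }
    patterns = set()
    for ubi, men, mqn, meng in itertools.product(
        ubi_variants.values(), men_variants.values(), mqn_variants.values(),
        (True, False),
    ):
        if ubi.status == pr.COMPLETE and not meng:
            continue  # inconsistent: UbiE/MenG is itself a Ubi role
        p = pr.infer_quinone_pattern(ubi, men, mqn, meng)
        patterns.add(p.quinones)
    return patterns


# ---------------------------------------------------------------------------
# displacement recovery

DEFAULT_RECOVERY_SCENARIOS: tuple[tuple[str, int], ...] = (
    ("ubiZ", 0), ("ubiZ", 1), ("ubiZ", 2), ("ubiZ", 3),
    ("menY", 0), ("menY", 1), ("menY", 2),
    ("mqnZ", 0), ("mqnZ", 1), ("mqnZ", 2),
)


def _planted_rank1(outdir: Path) -> tuple[bool, dict]:
    """Did the planted displacement family come out rank 1 for its gap?"""
    truth = json.loads((outdir / "truth.json").read_text())
    planted = truth["displacements"][0]
    fams = pd.read_csv(outdir / "families.tsv", sep="\t")
    truth_fams = truth["families"]
    planted_genes = {
        (g, gid)
        for g, genes in truth_fams.items()
        for gid, fam in genes.items()
        if fam == planted["family"]
    }
    inferred = {
        row.family_id
        for row in fams.itertuples()
        if (row.genome_id, row.gene_id) in planted_genes
    }
    cands = pd.read_csv(outdir / "candidates.tsv", sep="\t")
    role = planted["role_name"]
    sub = cands[(cands.pathway_id == planted["pathway_id"]) & (cands.role == role)]
    top = sub[sub["rank"] == 1]
    hit = bool(len(top)) and set(top.family) <= inferred and bool(inferred)
    detail = {
        "pathway": planted["pathway_id"],
        "role": role,
        "planted_family": planted["family"],
        "rank1_families": sorted(top.family) if len(top) else [],
        "recovered": hit,
    }
    return hit, detail


def displacement_recovery(
    scenarios: Sequence[tuple[str, int]] = DEFAULT_RECOVERY_SCENARIOS,
    base_seed: int = 100,
    workdir: Path | str | None = None,
) -> dict:
    """Run the full pipeline over seeded scenarios and score rank-1 recovery
    of the planted displacement families (precision and recall)."""
    own_tmp = workdir is None
    workdir = Path(tempfile.mkdtemp()) if own_tmp else Path(workdir)
    details = []
    hits = 0
    try:
        for i, (scenario, offset) in enumerate(scenarios):
            outdir = workdir / f"{scenario}_{offset}"
            run_pipeline(
                RunConfig(
                    outdir=str(outdir), seed=base_seed + offset,
                    scenario=scenario,
                )
            )
            hit, detail = _planted_rank1(outdir)
            hits += hit
            details.append({"scenario": scenario, **detail})
    finally:
        if own_tmp:
            shutil.rmtree(workdir, ignore_errors=True)
    n = len(scenarios)
    # one planted displacement per scenario: a miss is simultaneously a
    # false negative and (its gap's rank-1 being something else) a false call
    return {
        "n_scenarios": n,
        "n_recovered": hits,
        "precision": hits / n,
        "recall": hits / n,
        "details": details,
    }


# ---------------------------------------------------------------------------
# SDP benchmarks


def planted_sdp_alignment(
    seed: int,
    n_per_group: int = 10,
    n_sdp: int = 5,
    n_noise: int = 50,
    n_conserved: int = 5,
) -> tuple[sdp.MultipleAlignment, dict[str, str], list[int]]:
    """Two sequence groups differing deterministically at ``n_sdp`` columns,
    embedded in noise and invariant columns.  Returns the alignment, the
    true grouping, and the planted column indices.

    Noise columns vary over a small residue repertoire (2-4 residues with a
    dominant one), the way real protein-family columns do; uniform 20-way
    variability would be maximally adversarial and unlike any alignment.
    """
    rng = np.random.default_rng(seed)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    n = 2 * n_per_group
    cols = []
    for _ in range(n_sdp):
        r1, r2 = rng.choice(20, size=2, replace=False)
        cols.append([aa[r1]] * n_per_group + [aa[r2]] * n_per_group)
    for _ in range(n_noise):
        k = int(rng.integers(2, 5))
        repertoire = rng.choice(20, size=k, replace=False)
        weights = np.array([3.0] + [1.0] * (k - 1))
        picks = rng.choice(repertoire, size=n, p=weights / weights.sum())
        cols.append([aa[i] for i in picks])
    for _ in range(n_conserved):
        cols.append([aa[int(rng.integers(0, 20))]] * n)
    order = rng.permutation(len(cols))
    rows = ["".join(cols[c][r] for c in order) for r in range(n)]
    ids = [f"s{r:02d}" for r in range(n)]
    truth = {
        ids[r]: ("A" if r < n_per_group else "B") for r in range(n)
    }
    planted = [int(np.where(order == i)[0][0]) for i in range(n_sdp)]
    return sdp.MultipleAlignment(tuple(ids), tuple(rows)), truth, planted


def _same_partition(a: Mapping[str, str], b: Mapping[str, str]) -> bool:
    keys = sorted(a)
    la = [a[k] for k in keys]
    lb = [b[k] for k in keys]
    mapping: dict[str, str] = {}
    for x, y in zip(la, lb):
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


def sdp_group_recovery(n_bundles: int = 10, base_seed: int = 50) -> dict:
    """Fraction of restart bundles whose optimized grouping equals the
    planted two-group partition (up to label swap)."""
    recovered = 0
    for b in range(n_bundles):
        aln, truth, _ = planted_sdp_alignment(base_seed + b)
        grouping = sdp.optimize_groups(
            aln, n_groups=2, min_group_size=2, restarts=10, seed=base_seed + b
        )
        recovered += _same_partition(grouping.assignment, truth)
    return {"n_bundles": n_bundles, "n_recovered": recovered,
            "rate": recovered / n_bundles}


def sdp_type1_calibration(
    seed: int = 7, n_seqs: int = 30, n_cols: int = 60,
    n_shuffles: int = 300, alpha: float = 0.05,
) -> dict:
    """Significant-column rate on null data (no group signal at all)."""
    rng = np.random.default_rng(seed)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    rows = [
        "".join(aa[i] for i in rng.integers(0, 20, n_cols))
        for _ in range(n_seqs)
    ]
    ids = [f"s{r:02d}" for r in range(n_seqs)]
    aln = sdp.MultipleAlignment(tuple(ids), tuple(rows))
    grouping = {i: ("A" if r < n_seqs // 2 else "B") for r, i in enumerate(ids)}
    cols = sdp.call_sdps(aln, grouping, seed=seed, n_shuffles=n_shuffles,
                         alpha=alpha)
    n_sig = sum(c.significant for c in cols)
    rate = n_sig / len(cols)
    bound = alpha + 3 * (alpha * (1 - alpha) / len(cols)) ** 0.5
    return {"n_columns": len(cols), "n_significant": n_sig, "rate": rate,
            "alpha": alpha, "three_sigma_bound": bound,
            "calibrated": rate <= bound}


# ---------------------------------------------------------------------------
# homolog-group separation fixtures


def _family_leaf_seqs(
    n_leaves: int, depth: float, length: int, rng_seed: int
) -> dict[str, str]:
    tree = synthgen._load_tree(
        synthgen.ScenarioConfig(seed=rng_seed, n_genomes=n_leaves,
                                substitution_rate=depth)
    )
    rng = np.random.default_rng(rng_seed)
    return synthgen._evolve_family(tree, length, 1.0, 0.0, rng)


def separation_benchmark(seed: int = 5) -> dict:
    """Two canned topology fixtures.

    ``three_groups``: three deeply split families (UbiA/MqnP/MenA-style)
    must each come out monophyletic on the NJ tree.  ``mixed``: one family
    arbitrarily relabeled into two groups (UbiE/MenG-style) must come out
    non-monophyletic with the union flagged as a combined clade.
    """
    fams = {}
    for i, fam in enumerate(("UbiA", "MqnP", "MenA")):
        leaf_seqs = _family_leaf_seqs(6, 0.25, 120, seed + i)
        for leaf, s in leaf_seqs.items():
            fams[f"{fam}|{leaf}"] = s
    aln = phylo.progressive_align(fams)
    tree = phylo.midpoint_root(phylo.nj_tree(phylo.distance_matrix(aln)))
    labels = {name: name.split("|")[0] for name in fams}
    three = phylo.separation_report(tree, labels)

    # mixed fixture: a clean outgroup family plus one family whose members
    # get alternating labels - the labels cannot separate
    mixed_seqs = {}
    outgroup = _family_leaf_seqs(4, 0.25, 120, seed + 10)
    for leaf, s in outgroup.items():
        mixed_seqs[f"UbiE_out|{leaf}"] = s
    shared = _family_leaf_seqs(8, 0.25, 120, seed + 11)
    shared_labels = {}
    for i, (leaf, s) in enumerate(sorted(shared.items())):
        name = f"shared|{leaf}"
        mixed_seqs[name] = s
        shared_labels[name] = "MenG_like" if i % 2 == 0 else "MqnG_like"
    aln2 = phylo.progressive_align(mixed_seqs)
    tree2 = phylo.midpoint_root(phylo.nj_tree(phylo.distance_matrix(aln2)))
    labels2 = {
        name: ("UbiE" if name.startswith("UbiE_out") else shared_labels[name])
        for name in mixed_seqs
    }
    mixed = phylo.separation_report(tree2, labels2)
    return {
        "three_groups": three["monophyletic"],
        "three_groups_all_monophyletic": all(three["monophyletic"].values()),
        "mixed_groups": mixed["monophyletic"],
        "mixed_union_flagged": ("MenG_like", "MqnG_like") in
                               [tuple(p) for p in mixed["mixed_pairs"]],
    }


# ---------------------------------------------------------------------------
# determinism


def _tree_digest(root: Path) -> dict[str, str]:
    out = {}
    for path in sorted(root.rglob("*")):
        if path.is_file():
            out[str(path.relative_to(root))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    return out


def pipeline_determinism(seed: int = 21, scenario: str = "ubiZ",
                         workdir: Path | str | None = None) -> dict:
    """Run the full pipeline twice with one seed; compare output bytes."""
    own_tmp = workdir is None
    workdir = Path(tempfile.mkdtemp()) if own_tmp else Path(workdir)
    try:
        digests = []
        for rep in ("run1", "run2"):
            outdir = workdir / rep
            run_pipeline(
                RunConfig(outdir=str(outdir), seed=seed, scenario=scenario)
            )
            digests.append(_tree_digest(outdir))
        identical = digests[0] == digests[1]
        return {
            "identical": identical,
            "n_files": len(digests[0]),
            "differing": sorted(
                k for k in digests[0]
                if digests[1].get(k) != digests[0][k]
            ),
        }
    finally:
        if own_tmp:
            shutil.rmtree(workdir, ignore_errors=True)
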