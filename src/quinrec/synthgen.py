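"""Deterministic synthetic pan-genome generator with ground truth.

Emits the exact inputs the rest of the package consumes - per-genome protein
FASTA, GFF3 gene coordinates, domain-hit TSV - for a clade-structured cohort
in which every inference target is planted and recorded in a
:class:`TruthManifest`:

* pathway gene families present exactly in the planned clades, laid out as
  operon blocks (consecutive gene ranks) flanked by decoy genes;
* injected displacement families: the canonical family of one role deleted
  in a chosen clade, a novel family inserted exactly there, co-localized
  with the pathway operon and/or annotated as a two-domain fusion protein;
* reductase gene clusters placed with a configurable correlation to the
  genome's quinone capability;
* decoy families with clade-structured presence plus random gain/loss flips.

Protein sequences evolve from a random ancestor along the genome tree by
substitutions only (fixed length) at a configurable rate; an optional indel
rate exists for alignment stress tests.  Everything is driven by one seed;
reruns are byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode

from .genome_io import AnnotatedGenome, DomainHit, Gene, ProteinRecord, write_genome
from .pathway_recon import (
    MENG_FAMILY,
    classify_pathway,
    default_definitions,
    infer_quinone_pattern,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class DisplacementInjection:
    pathway_id: str
    role_name: str
    clade: str | tuple[str, ...]
    co_localize: bool = True
    fuse: bool = False
    fusion_partner_form: str | None = None  # role form whose domain rides along


@dataclass
class ScenarioConfig:
    seed: int
    n_genomes: int = 16
    tree_newick: str | None = None
    substitution_rate: float = 0.30   # expected substitutions/site root-to-tip
    indel_rate: float = 0.0           # per-branch deletion-event rate
    decoy_flip_prob: float = 0.08     # per-genome gain/loss noise on decoys
    pathway_plan: dict[str, object] = field(default_factory=dict)
    meng_plan: object = None          # extra menG carriers beyond the Ubi clade
    displacements: list[DisplacementInjection] = field(default_factory=list)
    reductase_plan: dict[str, float] = field(default_factory=dict)  # type -> rho
    reductase_subunits: dict[str, list[str]] = field(default_factory=dict)
    n_decoy_families: int = 25
    n_core_families: int = 3          # universal housekeeping-style families
    protein_length: int = 120
    mode: str = "legacy"
    domain_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("ScenarioConfig: seed is mandatory")
        for rate in (self.substitution_rate, self.indel_rate,
                     self.decoy_flip_prob):
            if rate < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class TruthManifest:
    families: dict[str, dict[str, str]]          # genome -> gene -> family
    pathway_calls: dict[str, dict[str, str]]     # genome -> pathway -> status
    quinone_patterns: dict[str, list[str]]       # genome -> sorted quinones
    displacements: list[dict]
    fusion_proteins: list[dict]
    codistribution: dict[str, str]               # genome -> both/neither/...
    reference_annotations: dict[str, list[str]]  # family -> [genome, gene]

    def family_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for genes in self.families.values():
            for fam in genes.values():
                sizes[fam] = sizes.get(fam, 0) + 1
        return sizes

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# tree handling

def balanced_tree_newick(n: int, total_depth_rate: float) -> str:
    """Balanced binary tree over leaves G01..Gnn with preorder-named internal
    nodes n1, n2, ... and equal per-level branch lengths summing to
    ``total_depth_rate`` root-to-tip."""
    leaves = [f"G{i:02d}" for i in range(1, n + 1)]
    depth = max(1, math.ceil(math.log2(n)))
    bl = total_depth_rate / depth
    counter = [0]

    def build(names: list[str]) -> str:
        if len(names) == 1:
            return f"{names[0]}:{bl:.6f}"
        counter[0] += 1
        me = f"n{counter[0]}"
        half = (len(names) + 1) // 2
        left, right = build(names[:half]), build(names[half:])
        return f"({left},{right}){me}:{bl:.6f}"

    return build(leaves) + ";"


def _load_tree(config: ScenarioConfig) -> TreeNode:
    nwk = config.tree_newick or balanced_tree_newick(
        config.n_genomes, config.substitution_rate
    )
    tree = TreeNode.read([nwk])
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = config.substitution_rate / 4
    return tree


def _clade_map(tree: TreeNode) -> dict[str, frozenset[str]]:
    out: dict[str, frozenset[str]] = {}
    for node in tree.traverse(include_self=True):
        tips = frozenset(
            t.name for t in (node.tips() if not node.is_tip() else [node])
        )
        if node.name:
            out[str(node.name)] = tips
    return out


def _resolve(spec: object, clades: Mapping[str, frozenset[str]],
             leaves: frozenset[str]) -> frozenset[str]:
    """A clade spec is an internal-node name, a leaf name, or an explicit
    iterable of genome ids."""
    if spec is None:
        return frozenset()
    if isinstance(spec, str):
        if spec not in clades:
            raise ValueError(f"clade {spec!r} not in tree")
        return clades[spec]
    genomes = frozenset(spec)
    unknown = genomes - leaves
    if unknown:
        raise ValueError(f"genomes not in tree: {sorted(unknown)}")
    return genomes


# ---------------------------------------------------------------------------
# sequence evolution

def _evolve_family(
    tree: TreeNode, length: int, rate_scale: float, indel_rate: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Ancestral random protein evolved to every leaf (substitutions; optional
    per-branch deletions)."""
    ancestral = rng.integers(0, 20, size=length)
    leaf_seqs: dict[str, str] = {}

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            bl = (child.length or 0.0) * rate_scale
            child_seq = seq.copy()
            p_mut = 1.0 - math.exp(-bl)
            hit = rng.random(child_seq.size) < p_mut
            n_hit = int(hit.sum())
            if n_hit:
                child_seq[hit] = (
                    child_seq[hit] + rng.integers(1, 20, size=n_hit)
                ) % 20
            if indel_rate > 0 and child_seq.size > 40:
                if rng.random() < 1.0 - math.exp(-indel_rate * max(bl, 1e-9)):
                    dlen = int(rng.integers(3, 10))
                    pos = int(rng.integers(0, child_seq.size - dlen))
                    child_seq = np.delete(
                        child_seq, np.arange(pos, pos + dlen)
                    )
            if child.is_tip():
                leaf_seqs[str(child.name)] = "".join(_AA[i] for i in child_seq)
            else:
                walk(child, child_seq)

    walk(tree, ancestral)
    return leaf_seqs


# ---------------------------------------------------------------------------
# the generator

def simulate(
    config: ScenarioConfig, outdir: Path | str | None = None
) -> tuple[list[AnnotatedGenome], TruthManifest]:
    """Build the cohort; optionally write the file bundle to ``outdir``."""
    rng = np.random.default_rng(config.seed)
    tree = _load_tree(config)
    clades = _clade_map(tree)
    leaves = frozenset(t.name for t in tree.tips())
    genome_ids = sorted(leaves)
    definitions = {d.pathway_id: d for d in default_definitions(config.mode)}

    # --- presence planning -------------------------------------------------
    pathway_genomes = {
        pid: _resolve(spec, clades, leaves)
        for pid, spec in sorted(config.pathway_plan.items())
    }
    for pid in pathway_genomes:
        if pid not in definitions:
            raise ValueError(f"pathway_plan: unknown pathway {pid!r}")

    # role form chosen per pathway: the first alternative of each role
    family_of_role: dict[tuple[str, str], str] = {}
    presence: dict[str, set[str]] = {}   # family -> genomes
    operon_layout: dict[str, list[str]] = {}  # pathway -> family order
    for pid, genomes_with in pathway_genomes.items():
        order: list[str] = []
        for role in definitions[pid].roles:
            fam = sorted(role.alternative_forms)[0]
            family_of_role[(pid, role.role_name)] = fam
            order.append(fam)
            if fam == MENG_FAMILY and pid != "Ubi":
                # the shared methyltransferase is planted only with Ubi (where
                # it is an obligate step) or via meng_plan - this is what makes
                # DMK-only genomes possible
                continue
            presence.setdefault(fam, set()).update(genomes_with)
        operon_layout[pid] = order

    meng_extra = _resolve(config.meng_plan, clades, leaves)
    if meng_extra:
        presence.setdefault(MENG_FAMILY, set()).update(meng_extra)

    # --- displacement injections ------------------------------------------
    injected: list[dict] = []
    for inj in config.displacements:
        if inj.pathway_id not in pathway_genomes:
            raise ValueError(
                f"displacement for pathway {inj.pathway_id!r} outside plan"
            )
        canonical = family_of_role.get((inj.pathway_id, inj.role_name))
        if canonical is None:
            raise ValueError(
                f"unknown role {inj.role_name!r} in {inj.pathway_id}"
            )
        gap = _resolve(inj.clade, clades, leaves) & pathway_genomes[inj.pathway_id]
        if not gap:
            raise ValueError(
                f"displacement clade {inj.clade!r} has no {inj.pathway_id} genomes"
            )
        novel = f"nd_{inj.role_name.replace('/', '_')}"
        presence[canonical] -= gap
        presence[novel] = set(gap)
        injected.append(
            {
                "pathway_id": inj.pathway_id,
                "role_name": inj.role_name,
                "family": novel,
                "displaced_family": canonical,
                "gap_genomes": sorted(gap),
                "co_localize": inj.co_localize,
                "fuse": inj.fuse,
                "fusion_partner_form": inj.fusion_partner_form,
            }
        )

    # --- reductase clusters -------------------------------------------------
    # quinone capability per genome from the *canonical* plan (displacement
    # gaps break the pathway until rediscovered, so they do not count)
    capable: dict[str, bool] = {}
    for g in genome_ids:
        ubi_ok = g in pathway_genomes.get("Ubi", frozenset()) and not any(
            g in i["gap_genomes"] for i in injected if i["pathway_id"] == "Ubi"
        )
        mkdmk = any(
            g in pathway_genomes.get(pid, frozenset())
            and not any(
                g in i["gap_genomes"] for i in injected if i["pathway_id"] == pid
            )
            for pid in ("Men", "Mqn_core", "Mqn_late")
        )
        capable[g] = ubi_ok or mkdmk

    reductase_families: dict[str, list[str]] = {}
    for rtype, rho in sorted(config.reductase_plan.items()):
        subunits = config.reductase_subunits.get(rtype, [f"{rtype.lower()}Q"])
        reductase_families[rtype] = subunits
        carriers = set()
        for g in genome_ids:
            if rng.random() < rho:
                present = capable[g]
            else:
                present = rng.random() < 0.5
            if present:
                carriers.add(g)
        for fam in subunits:
            presence.setdefault(fam, set()).update(carriers)

    # --- universal core families (every real genome has housekeeping genes;
    # they also guarantee no genome is ever empty) ---------------------------
    for i in range(config.n_core_families):
        presence[f"core{i + 1:03d}"] = set(genome_ids)

    # --- decoy families -----------------------------------------------------
    node_names = sorted(clades)
    for i in range(config.n_decoy_families):
        fam = f"dec{i + 1:03d}"
        base = set(clades[node_names[int(rng.integers(0, len(node_names)))]])
        for g in genome_ids:
            if rng.random() < config.decoy_flip_prob:
                base.symmetric_difference_update({g})
        if not base:
            base = {genome_ids[int(rng.integers(0, len(genome_ids)))]}
        presence[fam] = base

    presence = {f: set(g) for f, g in presence.items() if g}

    # --- sequences ----------------------------------------------------------
    fusion_partners = {
        i["family"]: family_of_role[(i["pathway_id"], i["fusion_partner_form"]
                                     or _default_partner(definitions, i))]
        for i in injected if i["fuse"]
    }
    seqs: dict[str, dict[str, str]] = {}
    for fam in sorted(presence):
        length = config.protein_length * (2 if fam in fusion_partners else 1)
        seqs[fam] = _evolve_family(
            tree, length, 1.0, config.indel_rate, rng
        )

    # --- genome assembly ----------------------------------------------------
    genomes = [
        _assemble_genome(
            g, config, presence, seqs, operon_layout, pathway_genomes,
            injected, reductase_families, fusion_partners, rng,
        )
        for g in genome_ids
    ]

    manifest = _build_manifest(
        genomes, presence, definitions, pathway_genomes, injected,
        fusion_partners, reductase_families, config,
    )
    if outdir is not None:
        write_bundle(genomes, manifest, outdir)
    return genomes, manifest


def _default_partner(definitions, inj) -> str:
    """Default fusion partner: the role next to the displaced one (the
    MenH-displacing MenY fuses with MenI, a pathway neighbor)."""
    names = [r.role_name for r in definitions[inj["pathway_id"]].roles]
    i = names.index(inj["role_name"])
    return names[i + 1] if i + 1 < len(names) else names[i - 1]


def _assemble_genome(
    genome_id: str,
    config: ScenarioConfig,
    presence: Mapping[str, set[str]],
    seqs: Mapping[str, Mapping[str, str]],
    operon_layout: Mapping[str, list[str]],
    pathway_genomes: Mapping[str, frozenset[str]],
    injected: list[dict],
    reductase_families: Mapping[str, list[str]],
    fusion_partners: Mapping[str, str],
    rng: np.random.Generator,
) -> AnnotatedGenome:
    """Lay families out on contigs: one operon contig per pathway present
    (decoy flanks around the operon block), everything else on c_misc."""
    my_families = sorted(f for f, gs in presence.items() if genome_id in gs)
    placed: set[str] = set()
    contigs: list[tuple[str, list[str]]] = []

    decoys = [f for f in my_families if f.startswith("dec")]
    flank_iter = iter(decoys)

    for pid in sorted(pathway_genomes):
        if genome_id not in pathway_genomes[pid]:
            continue
        # co-localized displacements slot in at the removed role's position
        slot_ins = {
            inj["displaced_family"]: inj["family"]
            for inj in injected
            if inj["pathway_id"] == pid
            and inj["co_localize"]
            and genome_id in inj["gap_genomes"]
        }
        block: list[str] = []
        for fam in operon_layout[pid]:
            if fam in slot_ins and slot_ins[fam] not in placed:
                block.append(slot_ins[fam])
                placed.add(slot_ins[fam])
            elif fam in my_families and fam not in placed:
                block.append(fam)
                placed.add(fam)
        left = [f for f in (next(flank_iter, None), next(flank_iter, None)) if f]
        right = [f for f in (next(flank_iter, None), next(flank_iter, None)) if f]
        placed.update(left + right)
        contigs.append((f"c_{pid}", left + block + right))

    cluster = [
        fam
        for rtype in sorted(reductase_families)
        for fam in reductase_families[rtype]
        if fam in my_families and fam not in placed
    ]
    placed.update(cluster)
    rest = [f for f in my_families if f not in placed]
    contigs.append(("c_misc", rest + cluster))

    genes: list[Gene] = []
    proteins: dict[str, ProteinRecord] = {}
    domains: list[DomainHit] = []
    truth: dict[str, str] = {}
    counter = 0
    for contig_id, fams in contigs:
        for pos, fam in enumerate(fams):
            counter += 1
            gid = f"{genome_id}_{counter:04d}"
            start = 1 + pos * 1000
            strand = "+" if rng.random() < 0.7 else "-"
            seq = seqs[fam][genome_id]
            genes.append(Gene(gid, contig_id, start, start + 899, strand, pos))
            proteins[gid] = ProteinRecord(gid, seq)
            truth[gid] = fam
            if not fam.startswith("dec"):
                label = config.domain_labels.get(fam, f"DOM_{fam}")
                half = len(seq) // 2
                if fam in fusion_partners:
                    partner = fusion_partners[fam]
                    p_label = config.domain_labels.get(
                        partner, f"DOM_{partner}"
                    )
                    domains.append(DomainHit(gid, label, 5, half - 10, 45.0))
                    domains.append(DomainHit(
                        gid, p_label, half + 10, len(seq) - 5, 45.0
                    ))
                else:
                    domains.append(DomainHit(
                        gid, label, 5, max(6, len(seq) - 15), 50.0
                    ))
    genome = AnnotatedGenome(genome_id, f"synthetic taxon {genome_id}",
                             genes, proteins, domains)
    genome.truth_families = truth  # attached for manifest assembly
    return genome


def _build_manifest(
    genomes: Sequence[AnnotatedGenome],
    presence: Mapping[str, set[str]],
    definitions,
    pathway_genomes,
    injected,
    fusion_partners,
    reductase_families,
    config: ScenarioConfig,
) -> TruthManifest:
    families = {g.genome_id: dict(sorted(g.truth_families.items()))
                for g in genomes}
    calls: dict[str, dict[str, str]] = {}
    patterns: dict[str, list[str]] = {}
    codist: dict[str, str] = {}
    defs = {d.pathway_id: d for d in default_definitions(config.mode)}
    for g in genomes:
        row = {fam: g.genome_id in presence.get(fam, set()) for fam in presence}
        gcalls = {
            pid: classify_pathway(g.genome_id, row, d) for pid, d in defs.items()
        }
        calls[g.genome_id] = {pid: c.status for pid, c in gcalls.items()}
        pattern = infer_quinone_pattern(
            gcalls["Ubi"], gcalls["Men"], gcalls["Mqn_core"],
            row.get(MENG_FAMILY, False),
        )
        patterns[g.genome_id] = sorted(pattern.quinones)
        has_reductase = any(
            all(row.get(f, False) for f in subs)
            for subs in reductase_families.values()
        )
        has_quinone = bool(pattern.quinones)
        codist[g.genome_id] = (
            "both" if has_reductase and has_quinone
            else "reductase_only" if has_reductase
            else "quinone_only" if has_quinone
            else "neither"
        )

    fusions = []
    for g in genomes:
        for gid, fam in g.truth_families.items():
            if fam in fusion_partners:
                fusions.append({
                    "genome_id": g.genome_id,
                    "gene_id": gid,
                    "family": fam,
                    "domains": [h.domain_acc for h in g.domains_of(gid)],
                })

    novel = {i["family"] for i in injected}
    ref: dict[str, list[str]] = {}
    for g in genomes:
        for gid, fam in sorted(g.truth_families.items()):
            if fam.startswith("dec") or fam in novel:
                continue
            key = (g.genome_id, gid)
            if fam not in ref or key < tuple(ref[fam]):
                ref[fam] = [g.genome_id, gid]

    return TruthManifest(
        families=families,
        pathway_calls=calls,
        quinone_patterns=patterns,
        displacements=injected,
        fusion_proteins=fusions,
        codistribution=codist,
        reference_annotations=ref,
    )


def write_bundle(
    genomes: Sequence[AnnotatedGenome], manifest: TruthManifest,
    outdir: Path | str,
) -> Path:
    outdir = Path(outdir)
    gdir = outdir / "genomes"
    gdir.mkdir(parents=True, exist_ok=True)
    for genome in genomes:
        write_genome(genome, gdir)
    (outdir / "truth.json").write_text(manifest.to_json() + "\n")
    (outdir / "reference_annotations.json").write_text(
        json.dumps(manifest.reference_annotations, indent=1, sort_keys=True)
        + "\n"
    )
    return outdir


# ---------------------------------------------------------------------------
# canned discovery-archetype scenarios (<= 30 genomes, <= 200 families)

def ubiZ_config(seed: int) -> ScenarioConfig:
    """Occurrence + co-localization archetype: the UbiD/UbiX role displaced
    in a 4-genome subclade of an 8-genome Ubi clade, the novel family sitting
    inside the Ubi operon."""
    return ScenarioConfig(
        seed=seed,
        n_genomes=16,
        pathway_plan={"Ubi": "n2", "Men": "n10"},
        meng_plan="n11",
        displacements=[
            DisplacementInjection("Ubi", "UbiD/UbiX", "n3", co_localize=True)
        ],
        reductase_plan={"Frd": 1.0},
    )


def menY_config(seed: int) -> ScenarioConfig:
    """Fusion archetype: MenH displaced; the novel family's proteins carry
    their own domain plus the MenI-diagnostic domain (Rosetta stone)."""
    cfg = ScenarioConfig(
        seed=seed,
        n_genomes=16,
        pathway_plan={"Men": "n2"},
        meng_plan="n2",
        displacements=[
            DisplacementInjection(
                "Men", "MenH", "n3", co_localize=False, fuse=True,
                fusion_partner_form="MenI",
            )
        ],
        reductase_plan={"Frd": 1.0},
        domain_labels={"nd_MenH": "PF08282", "menI": "PF03061"},
    )
    return cfg


def mqnZ_config(seed: int) -> ScenarioConfig:
    """Operon-context archetype: MqnD displaced, novel family co-localized
    with the mqnC/mqnE genes in every gap genome."""
    return ScenarioConfig(
        seed=seed,
        n_genomes=16,
        pathway_plan={"Mqn_core": "n2", "Men": "n10"},
        meng_plan="n9",
        displacements=[
            DisplacementInjection("Mqn_core", "MqnD", "n3", co_localize=True)
        ],
        reductase_plan={"Frd": 1.0},
    )


def cohort_config(seed: int, rho: float = 1.0, n_genomes: int = 16,
                  n_decoys: int = 20) -> ScenarioConfig:
    """A cohort expressing all five quinone-synthesis patterns, with a
    reductase cluster correlated (rho) with quinone capability."""
    g = [f"G{i:02d}" for i in range(1, n_genomes + 1)]
    q = max(4, n_genomes // 4)
    return ScenarioConfig(
        seed=seed,
        n_genomes=n_genomes,
        pathway_plan={
            "Ubi": tuple(g[: 2 * q]),
            "Men": tuple(g[:q] + g[2 * q : 3 * q]),
        },
        meng_plan=tuple(g[2 * q : 2 * q + q // 2]),
        reductase_plan={"Frd": rho},
        n_decoy_families=n_decoys,
    )


def emit_ubiZ_scenario(seed: int, outdir: Path | str):
    return simulate(ubiZ_config(seed), outdir)


def emit_menY_scenario(seed: int, outdir: Path | str):
    return simulate(menY_config(seed), outdir)


def emit_mqnZ_scenario(seed: int, outdir: Path | str):
    return simulate(mqnZ_config(seed), outdir)
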