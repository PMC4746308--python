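"""End-to-end orchestration: files in, stage outputs and a summary out.

Stages run in a fixed order - genomes -> orthology -> pathway
reconstruction -> displacement -> co-distribution (phylogeny/SDP evidence
runs through its own subcommands on exported family sequences) - handing
data to each other through flat files in the run directory, so any stage
can be rerun or replaced independently:

    genomes/*.faa|gff|domains.tsv   input bundle (or synthgen output)
    reference_annotations.json      role seed genes for annotation transfer
    families.tsv, presence.tsv      orthology stage
    family_labels.tsv, pathway_calls.tsv, patterns.tsv, census.tsv
    gaps.tsv, candidates.tsv        displacement stage
    codist.tsv, codist_summary.json co-distribution stage
    summary.json                    aggregated machine-readable report

Role labels reach inferred families by annotation transfer: a family
containing a reference-annotated seed gene (model-organism style) inherits
that gene's family label.  A rerun with the same config and seed reproduces
every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import codistribution as codist_mod
from . import displacement as disp_mod
from . import orthology as orth_mod
from . import pathway_recon as path_mod
from . import synthgen
from .genome_io import AnnotatedGenome, read_genome, read_presence_matrix, \
    write_presence_matrix

log = logging.getLogger("quinrec")

SCENARIOS = {
    "ubiZ": synthgen.ubiZ_config,
    "menY": synthgen.menY_config,
    "mqnZ": synthgen.mqnZ_config,
    "cohort": synthgen.cohort_config,
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    scenario: str | None = None
    input_dir: str | None = None
    mode: str = "legacy"
    orthology: dict = field(default_factory=dict)
    displacement: dict = field(default_factory=dict)
    codist: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.scenario is None and self.input_dir is None:
            raise PipelineError("config needs either 'scenario' or 'input_dir'")
        if self.scenario is not None and self.scenario not in SCENARIOS:
            raise PipelineError(
                f"unknown scenario {self.scenario!r}; choose from "
                f"{sorted(SCENARIOS)}"
            )
        if self.mode not in {"legacy", "extended"}:
            raise PipelineError(f"unknown mode {self.mode!r}")
        known_orth = {f.name for f in dataclasses.fields(orth_mod.OrthologyParams)}
        bad = set(self.orthology) - known_orth
        if bad:
            raise PipelineError(f"unknown orthology params: {sorted(bad)}")
        bad = set(self.displacement) - {"max_missing", "max_intervening",
                                        "weights", "top_n"}
        if bad:
            raise PipelineError(f"unknown displacement params: {sorted(bad)}")
        bad = set(self.codist) - {"catalog"}
        if bad:
            raise PipelineError(f"unknown codist params: {sorted(bad)}")


# ---------------------------------------------------------------------------
# genome loading

def load_genome_dir(genomes_dir: Path | str) -> list[AnnotatedGenome]:
    genomes_dir = Path(genomes_dir)
    fastas = sorted(genomes_dir.glob("*.faa"))
    if not fastas:
        raise PipelineError(f"no *.faa genomes found in {genomes_dir}")
    out = []
    for fasta in fastas:
        stem = fasta.stem
        gff = genomes_dir / f"{stem}.gff"
        dom = genomes_dir / f"{stem}.domains.tsv"
        if not gff.exists():
            raise PipelineError(f"missing gene coordinates {gff}")
        out.append(
            read_genome(fasta, gff, dom if dom.exists() else None, genome_id=stem)
        )
    return out


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: RunConfig) -> Path:
    out = Path(config.outdir)
    factory = SCENARIOS[config.scenario]
    scenario_cfg = factory(config.seed)
    log.info("[simulate] scenario=%s seed=%d", config.scenario, config.seed)
    synthgen.simulate(scenario_cfg, out)
    return out


def stage_orthology(
    genomes: Sequence[AnnotatedGenome], params: orth_mod.OrthologyParams,
    outdir: Path,
) -> pd.DataFrame:
    if not genomes:
        raise PipelineError("empty genome set")
    log.info("[orthology] %d genomes", len(genomes))
    from itertools import combinations
    pairs = [
        p for ga, gb in combinations(genomes, 2)
        for p in orth_mod.call_bbh(ga, gb, params)
    ]
    catalog = orth_mod.build_families(genomes, params, pairs=pairs)
    matrix = orth_mod.presence_matrix(catalog, genomes)
    orth_mod.pairs_table(pairs).to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    orth_mod.family_table(catalog).to_csv(
        outdir / "families.tsv", sep="\t", index=False
    )
    write_presence_matrix(matrix, outdir / "presence.tsv")
    return matrix


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise PipelineError(
            f"missing {path.name}; run the '{producer}' stage first"
        )
    return path


def label_families(
    families: pd.DataFrame, reference: Mapping[str, Sequence[str]]
) -> dict[str, str]:
    """family_id -> role label via reference seed genes."""
    by_gene = {
        (row.genome_id, row.gene_id): row.family_id
        for row in families.itertuples()
    }
    labels: dict[str, str] = {}
    for label, (genome_id, gene_id) in sorted(reference.items()):
        fam = by_gene.get((genome_id, gene_id))
        if fam is None:
            raise PipelineError(
                f"reference gene {genome_id}:{gene_id} ({label}) not in any family"
            )
        labels[fam] = label
    return labels


def _labeled_presence(
    matrix: pd.DataFrame, labels: Mapping[str, str]
) -> pd.DataFrame:
    """label x genome boolean matrix (a label is present when any family
    carrying it is)."""
    rows = {}
    for fam, label in sorted(labels.items()):
        row = matrix.loc[fam]
        rows[label] = rows[label] | row if label in rows else row.copy()
    return pd.DataFrame(rows).T.astype(bool)


def stage_reconstruct(outdir: Path, mode: str) -> dict:
    matrix = read_presence_matrix(_require(outdir / "presence.tsv", "orthology"))
    families = pd.read_csv(_require(outdir / "families.tsv", "orthology"), sep="\t")
    ref_path = _require(outdir / "reference_annotations.json", "simulate")
    reference = json.loads(ref_path.read_text())
    labels = label_families(families, reference)
    pd.DataFrame(
        sorted(labels.items()), columns=["family_id", "label"]
    ).to_csv(outdir / "family_labels.tsv", sep="\t", index=False)

    labeled = _labeled_presence(matrix, labels)
    definitions = path_mod.default_definitions(mode)
    calls, patterns = [], []
    for genome_id in labeled.columns:
        row = labeled[genome_id].to_dict()
        gcalls = {
            d.pathway_id: path_mod.classify_pathway(genome_id, row, d)
            for d in definitions
        }
        calls.extend(gcalls.values())
        patterns.append(
            path_mod.infer_quinone_pattern(
                gcalls["Ubi"], gcalls["Men"], gcalls["Mqn_core"],
                row.get(path_mod.MENG_FAMILY, False),
            )
        )
    log.info("[reconstruct] %d pathway calls", len(calls))
    path_mod.calls_table(calls).to_csv(
        outdir / "pathway_calls.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(p.genome_id, path_mod.pattern_name(p)) for p in patterns],
        columns=["genome_id", "pattern"],
    ).to_csv(outdir / "patterns.tsv", sep="\t", index=False)
    census = path_mod.pattern_census(patterns)
    census.to_csv(outdir / "census.tsv", sep="\t", index=False)
    return {"calls": calls, "patterns": patterns, "labels": labels}


def stage_displace(
    outdir: Path,
    genomes: Sequence[AnnotatedGenome],
    mode: str,
    max_missing: int = 1,
    max_intervening: int = 3,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    top_n: int = 30,
) -> list[disp_mod.CandidateDisplacement]:
    matrix = read_presence_matrix(_require(outdir / "presence.tsv", "orthology"))
    _require(outdir / "pathway_calls.tsv", "reconstruct")
    labels_df = pd.read_csv(
        _require(outdir / "family_labels.tsv", "reconstruct"), sep="\t"
    )
    labels = dict(zip(labels_df.family_id, labels_df.label))
    families = pd.read_csv(outdir / "families.tsv", sep="\t")
    members: dict[str, list[tuple[str, str]]] = {}
    for row in families.itertuples():
        members.setdefault(row.family_id, []).append((row.genome_id, row.gene_id))

    labeled = _labeled_presence(matrix, labels)
    definitions = {d.pathway_id: d for d in path_mod.default_definitions(mode)}
    calls = []
    for genome_id in labeled.columns:
        row = labeled[genome_id].to_dict()
        calls.extend(
            path_mod.classify_pathway(genome_id, row, d)
            for d in definitions.values()
        )
    gaps = disp_mod.find_gaps(calls, max_missing=max_missing)
    log.info("[displace] %d gaps", len(gaps))
    genome_map = {g.genome_id: g for g in genomes}
    all_candidates: list[disp_mod.CandidateDisplacement] = []
    for gap in gaps:
        definition = definitions[gap.pathway_id]
        role_forms = {
            f for r in definition.roles if r.role_name == gap.role_name
            for f in r.alternative_forms
        }
        exclude = {fam for fam, lab in labels.items() if lab in role_forms}
        profiles = disp_mod.profile_match(gap, matrix, exclude_families=exclude)
        profiles.sort(key=lambda p: (p.p_value, p.candidate_family))
        short = profiles[:top_n]
        pathway_forms = {
            f for r in definition.roles for f in r.alternative_forms
        }
        pathway_fams = {f for f, lab in labels.items() if lab in pathway_forms}
        pathway_genes = {
            gn: {
                gid for fam in pathway_fams
                for g2, gid in members.get(fam, []) if g2 == gn
            }
            for gn in matrix.columns
        }
        role_domains = {
            h.domain_acc
            for fam in pathway_fams
            for gn, gid in members.get(fam, [])
            for h in genome_map[gn].domains_of(gid)
        }
        colocs, fusions = {}, {}
        for prof in short:
            fam = prof.candidate_family
            colocs[fam] = disp_mod.colocalization(
                members.get(fam, []), pathway_genes, genome_map,
                max_intervening=max_intervening,
            )
            cand_domains = {
                h.domain_acc
                for gn, gid in members.get(fam, [])
                for h in genome_map[gn].domains_of(gid)
            } - role_domains
            if cand_domains:
                fusions[fam] = [
                    ev for ev in disp_mod.fusion_scan(
                        cand_domains, role_domains, genomes
                    )
                    if ev.protein_id.split(":", 1)[0] in gap.gap_genomes
                ]
        all_candidates.extend(
            disp_mod.rank_candidates(gap, short, colocs, fusions, weights)
        )
    pd.DataFrame(
        [(g.pathway_id, g.role_name, len(g.gap_genomes),
          ",".join(sorted(g.gap_genomes))) for g in gaps],
        columns=["pathway_id", "role", "n_gap_genomes", "gap_genomes"],
    ).to_csv(outdir / "gaps.tsv", sep="\t", index=False)
    disp_mod.candidates_table(all_candidates).to_csv(
        outdir / "candidates.tsv", sep="\t", index=False
    )
    return all_candidates


def stage_codist(outdir: Path, catalog_path: str | None = None) -> dict:
    matrix = read_presence_matrix(_require(outdir / "presence.tsv", "orthology"))
    labels_df = pd.read_csv(
        _require(outdir / "family_labels.tsv", "reconstruct"), sep="\t"
    )
    patterns_df = pd.read_csv(
        _require(outdir / "patterns.tsv", "reconstruct"), sep="\t"
    )
    labels = dict(zip(labels_df.family_id, labels_df.label))
    labeled = _labeled_presence(matrix, labels)
    catalog = codist_mod.load_reductase_catalog(catalog_path)
    calls = []
    for row in patterns_df.itertuples():
        quinones = frozenset() if row.pattern == "none" else frozenset(
            row.pattern.split("+")
        )
        pattern = path_mod.QuinonePattern(row.genome_id, quinones)
        presence = (
            labeled[row.genome_id].to_dict() if row.genome_id in labeled else {}
        )
        calls.append(
            codist_mod.classify_codistribution(pattern, presence, catalog)
        )
    stats = codist_mod.agreement_stats(calls)
    codist_mod.calls_table(calls).to_csv(
        outdir / "codist.tsv", sep="\t", index=False
    )
    (outdir / "codist_summary.json").write_text(
        json.dumps(stats, indent=1, sort_keys=True) + "\n"
    )
    log.info("[codist] agreement %.1f%%", stats["agreement_percent"])
    return stats


def build_summary(outdir: Path) -> dict:
    """Aggregate per-stage outputs into one machine-readable summary."""
    outdir = Path(outdir)
    calls = pd.read_csv(_require(outdir / "pathway_calls.tsv", "reconstruct"),
                        sep="\t")
    census = pd.read_csv(outdir / "census.tsv", sep="\t")
    cands = pd.read_csv(_require(outdir / "candidates.tsv", "displace"),
                        sep="\t")
    gaps = pd.read_csv(outdir / "gaps.tsv", sep="\t")
    codist = json.loads((outdir / "codist_summary.json").read_text())
    matrix = read_presence_matrix(outdir / "presence.tsv")

    status_counts = (
        calls.groupby(["pathway_id", "status"]).size().to_dict()
    )
    gap_reports = []
    for g in gaps.itertuples():
        sub = cands[
            (cands.pathway_id == g.pathway_id) & (cands.role == g.role)
        ].sort_values(["rank", "family"])
        top = sub.iloc[0] if len(sub) else None
        gap_reports.append({
            "pathway_id": g.pathway_id,
            "role": g.role,
            "n_gap_genomes": int(g.n_gap_genomes),
            "top_candidate": None if top is None else {
                "family": top.family,
                "p_value": float(top.p_value),
                "exact_match": bool(top.exact_match),
                "combined_score": float(top.combined_score),
                "rank": int(top["rank"]),
            },
        })
    summary = {
        "n_genomes": int(matrix.shape[1]),
        "n_families": int(matrix.shape[0]),
        "pathway_status_counts": {
            f"{pid}:{status}": int(n) for (pid, status), n in
            sorted(status_counts.items())
        },
        "pattern_census": {
            row.pattern: int(row.n_genomes) for row in census.itertuples()
        },
        "gaps": gap_reports,
        "codistribution": codist,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    return summary


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; abort on failure with the stage named
    and a FAILED marker left next to any partial outputs."""
    config.validate()
    logging.basicConfig(
        level=config.log_level,
        format="%(asctime)s %(name)s %(message)s",
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = orth_mod.OrthologyParams(**config.orthology)
    stage = "setup"
    try:
        if config.scenario is not None:
            stage = "simulate"
            stage_simulate(config)
            genomes_dir = outdir / "genomes"
        else:
            genomes_dir = Path(config.input_dir) / "genomes"
            ref = Path(config.input_dir) / "reference_annotations.json"
            if ref.exists() and not (outdir / "reference_annotations.json").exists():
                (outdir / "reference_annotations.json").write_text(ref.read_text())
        stage = "io"
        genomes = load_genome_dir(genomes_dir)
        if not genomes:
            raise PipelineError("empty genome set")
        stage = "orthology"
        stage_orthology(genomes, params, outdir)
        stage = "reconstruct"
        stage_reconstruct(outdir, config.mode)
        stage = "displace"
        stage_displace(outdir, genomes, config.mode, **{
            k: tuple(v) if k == "weights" else v
            for k, v in config.displacement.items()
        })
        stage = "codist"
        stage_codist(outdir, config.codist.get("catalog"))
        stage = "report"
        return build_summary(outdir)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
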