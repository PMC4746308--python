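"""Annotated-genome data model and flat-file readers/writers.

The unit of analysis throughout the package is an :class:`AnnotatedGenome`:
ordered genes on contigs, their protein sequences, and protein-domain hits.
Chromosomal co-localization logic elsewhere works on *gene rank* (number of
intervening genes), not base pairs, so draft-genome coordinate noise does not
matter; ranks are assigned here by sorting on (contig, start).

Formats: protein FASTA (Bio.SeqIO), a GFF3 subset (feature types ``gene`` or
``CDS`` with an ``ID`` attribute), a tab-separated domain-hit table with
header ``gene_id  domain_acc  start  end  score``, and a families x genomes
0/1 presence matrix as TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
from Bio import SeqIO

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")
GFF_FEATURE_TYPES = {"gene", "CDS"}


class GenomeIOError(ValueError):
    """Raised on malformed or inconsistent genome input files."""


@dataclass(frozen=True, order=True)
class Gene:
    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeIOError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise GenomeIOError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class ProteinRecord:
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeIOError(f"protein {self.gene_id}: empty sequence")
        seq = self.sequence
        if not seq.isupper() or not set(seq) <= VALID_AA:
            bad = sorted(set(seq) - VALID_AA) or "lowercase letters"
            raise GenomeIOError(f"protein {self.gene_id}: invalid residues {bad}")


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    domain_acc: str
    start_aa: int
    end_aa: int
    score: float

    def __post_init__(self) -> None:
        if not (1 <= self.start_aa <= self.end_aa):
            raise GenomeIOError(
                f"domain hit {self.domain_acc} on {self.gene_id}: bad span "
                f"{self.start_aa}..{self.end_aa}"
            )


@dataclass
class AnnotatedGenome:
    """Genes with order, protein sequences and domain annotations.

    Invariant (checked in ``__post_init__``): every protein and every domain
    hit resolves to a gene; gene ids are unique; per-contig ranks are a
    permutation of ``0..n-1``.
    """

    genome_id: str
    taxon_label: str = ""
    genes: list[Gene] = field(default_factory=list)
    proteins: dict[str, ProteinRecord] = field(default_factory=dict)
    domains: list[DomainHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GenomeIOError(f"genome {self.genome_id}: duplicate gene ids {dup}")
        known = set(ids)
        for gid in self.proteins:
            if gid not in known:
                raise GenomeIOError(
                    f"genome {self.genome_id}: protein record for unknown gene {gid!r}"
                )
        for hit in self.domains:
            if hit.gene_id not in known:
                raise GenomeIOError(
                    f"genome {self.genome_id}: domain hit for unknown gene "
                    f"{hit.gene_id!r}"
                )
            prot = self.proteins.get(hit.gene_id)
            if prot is not None and hit.end_aa > len(prot.sequence):
                raise GenomeIOError(
                    f"genome {self.genome_id}: domain {hit.domain_acc} ends at "
                    f"{hit.end_aa} beyond protein {hit.gene_id} "
                    f"(length {len(prot.sequence)})"
                )
        self._by_id = {g.gene_id: g for g in self.genes}

    def gene(self, gene_id: str) -> Gene:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"genome {self.genome_id}: no gene {gene_id!r}") from None

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def contig_genes(self, contig_id: str) -> list[Gene]:
        """Genes on one contig in rank order."""
        return sorted(
            (g for g in self.genes if g.contig_id == contig_id),
            key=lambda g: g.rank,
        )

    def neighbors(self, gene_id: str, window: int) -> list[Gene]:
        """Genes within ``window`` ranks of ``gene_id`` on the same contig."""
        g = self.gene(gene_id)
        return [
            other
            for other in self.genes
            if other.contig_id == g.contig_id
            and other.gene_id != gene_id
            and abs(other.rank - g.rank) <= window
        ]

    def domains_of(self, gene_id: str) -> list[DomainHit]:
        return sorted(
            (h for h in self.domains if h.gene_id == gene_id),
            key=lambda h: (h.start_aa, h.end_aa, h.domain_acc),
        )


def _assign_ranks(raw: list[tuple[str, str, int, int, str]]) -> list[Gene]:
    # rank = 0-based position in (contig, start, gene_id) sort order, per contig
    genes: list[Gene] = []
    ordered = sorted(raw, key=lambda t: (t[1], t[2], t[0]))
    counters: dict[str, int] = {}
    for gene_id, contig, start, end, strand in ordered:
        rank = counters.get(contig, 0)
        counters[contig] = rank + 1
        genes.append(Gene(gene_id, contig, start, end, strand, rank))
    return genes


def _parse_gff3(path: Path) -> list[tuple[str, str, int, int, str]]:
    rows = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GenomeIOError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(parts)}"
                )
            contig, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = parts
            if ftype not in GFF_FEATURE_TYPES:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GenomeIOError(
                    f"{path}:{lineno}: malformed coordinates {start_s!r}..{end_s!r}"
                ) from None
            if start < 1 or start > end:
                raise GenomeIOError(
                    f"{path}:{lineno}: invalid coordinate range {start}..{end}"
                )
            gene_id = None
            for chunk in attrs.split(";"):
                key, _, value = chunk.strip().partition("=")
                if key == "ID" and value:
                    gene_id = value
                    break
            if gene_id is None:
                raise GenomeIOError(f"{path}:{lineno}: feature without ID attribute")
            if gene_id in seen:  # a gene + its CDS: keep first occurrence
                continue
            seen.add(gene_id)
            if strand not in {"+", "-"}:
                raise GenomeIOError(
                    f"{path}:{lineno}: bad strand {strand!r} for {gene_id}"
                )
            rows.append((gene_id, contig, start, end, strand))
    return rows


def read_domain_tsv(path: Path | str) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "domain_acc": str})
    required = ["gene_id", "domain_acc", "start", "end", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GenomeIOError(f"{path}: missing columns {missing}")
    return [
        DomainHit(r.gene_id, r.domain_acc, int(r.start), int(r.end), float(r.score))
        for r in df.itertuples()
    ]


def read_genome(
    fasta_path: Path | str,
    gff_path: Path | str,
    domain_tsv_path: Path | str | None = None,
    genome_id: str | None = None,
    taxon_label: str = "",
) -> AnnotatedGenome:
    """Load one genome from protein FASTA + GFF3 (+ optional domain TSV).

    Every FASTA record id must resolve to a GFF gene id and vice versa;
    unresolvable ids and malformed coordinates are hard errors.
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    if genome_id is None:
        genome_id = fasta_path.stem.removesuffix(".faa")
    raw = _parse_gff3(gff_path)
    genes = _assign_ranks(raw)
    gene_ids = {g.gene_id for g in genes}

    proteins: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in gene_ids:
            raise GenomeIOError(
                f"{fasta_path}: FASTA record {rec.id!r} has no gene in {gff_path}"
            )
        proteins[rec.id] = ProteinRecord(rec.id, str(rec.seq).upper())
    absent = sorted(gene_ids - proteins.keys())
    if absent:
        raise GenomeIOError(f"{fasta_path}: no protein sequence for genes {absent}")

    domains = read_domain_tsv(domain_tsv_path) if domain_tsv_path else []
    return AnnotatedGenome(genome_id, taxon_label, genes, proteins, domains)


# ---------------------------------------------------------------------------
# presence matrix (families x genomes, boolean)

def write_presence_matrix(matrix: pd.DataFrame, path: Path | str) -> None:
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise GenomeIOError("presence matrix has duplicate row or column labels")
    out = matrix.astype(int)
    out.index.name = "family"
    out.to_csv(path, sep="\t")


def read_presence_matrix(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = sorted(df.index[df.index.duplicated()].unique())
        raise GenomeIOError(f"{path}: duplicate family rows {dup}")
    return df.astype(bool)


def write_genome(genome: AnnotatedGenome, outdir: Path | str, stem: str | None = None
                 ) -> dict[str, Path]:
    """Emit FASTA/GFF3/domain-TSV for one genome (synthgen and fixtures)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or genome.genome_id
    fasta = outdir / f"{stem}.faa"
    gff = outdir / f"{stem}.gff"
    dom = outdir / f"{stem}.domains.tsv"

    with open(fasta, "w") as fh:
        for gid in sorted(genome.proteins):
            fh.write(f">{gid}\n{genome.proteins[gid].sequence}\n")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genome.genes, key=lambda g: (g.contig_id, g.start)):
            fh.write(
                f"{g.contig_id}\tquinrec\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t."
                f"\tID={g.gene_id}\n"
            )
    rows = sorted(
        genome.domains, key=lambda h: (h.gene_id, h.start_aa, h.domain_acc)
    )
    with open(dom, "w") as fh:
        fh.write("gene_id\tdomain_acc\tstart\tend\tscore\n")
        for h in rows:
            fh.write(
                f"{h.gene_id}\t{h.domain_acc}\t{h.start_aa}\t{h.end_aa}\t{h.score:g}\n"
            )
    return {"fasta": fasta, "gff": gff, "domains": dom}
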