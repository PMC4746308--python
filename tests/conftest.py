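"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from quinrec.genome_io import AnnotatedGenome, DomainHit, Gene, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


def build_genome(
    genome_id: str,
    layout: dict[str, list[tuple[str, str]]],
    domains: list[DomainHit] | None = None,
) -> AnnotatedGenome:
    """Genome from ``{contig: [(gene_id, protein_seq), ...]}`` with
    coordinates assigned in listing order."""
    genes, proteins = [], {}
    for contig, entries in layout.items():
        for rank, (gene_id, seq) in enumerate(entries):
            start = 1 + rank * 1000
            genes.append(Gene(gene_id, contig, start, start + 899, "+", rank))
            proteins[gene_id] = ProteinRecord(gene_id, seq)
    return AnnotatedGenome(genome_id, "", genes, proteins, domains or [])


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, length))


def mutate(rng: np.random.Generator, seq: str, p: float) -> str:
    out = []
    for c in seq:
        if rng.random() < p:
            out.append(AA[(AA.index(c) + int(rng.integers(1, 20))) % 20])
        else:
            out.append(c)
    return "".join(out)


@pytest.fixture(scope="session")
def ubiz_bundle(tmp_path_factory) -> Path:
    """One ubiZ-scenario file bundle shared across tests."""
    from quinrec import synthgen

    outdir = tmp_path_factory.mktemp("ubiz_bundle")
    synthgen.emit_ubiZ_scenario(seed=11, outdir=outdir)
    return outdir
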