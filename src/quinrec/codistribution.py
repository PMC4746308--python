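"""Co-distribution of quinone capability and quinone-dependent reductases.

Respiration closes a loop: a quinone-dependent terminal reductase is only
useful in a genome that can make (or import) a compatible quinone, and a
quinone pathway with no reductase to feed suggests an incomplete picture.
Cross-tabulating the two repertoires per genome gives a four-way
classification - both / neither (agreement), reductase_only / quinone_only
(disagreement) - plus quinone-specific conflicts such as a UQ-only oxidase
in an MK-only genome.

The reductase catalog (17 default types) is configuration: which membrane
subunit families mark a type as present, and which quinones it accepts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .pathway_recon import QuinonePattern

BOTH, NEITHER, REDUCTASE_ONLY, QUINONE_ONLY = (
    "both", "neither", "reductase_only", "quinone_only",
)
CATEGORIES = (BOTH, NEITHER, REDUCTASE_ONLY, QUINONE_ONLY)


@dataclass(frozen=True)
class ReductaseType:
    name: str
    acceptor: str
    subunit_families: tuple[str, ...]
    compatible_quinones: frozenset[str]

    def __post_init__(self) -> None:
        if not self.subunit_families:
            raise ValueError(f"reductase {self.name}: no subunit families")
        if not self.compatible_quinones:
            raise ValueError(f"reductase {self.name}: no compatible quinones")


@dataclass(frozen=True)
class CodistCall:
    genome_id: str
    category: str
    present_reductases: tuple[str, ...]
    conflicts: tuple[str, ...]  # reductases with no producible compatible quinone


def load_reductase_catalog(
    config: Mapping | Path | str | None = None,
) -> dict[str, ReductaseType]:
    """Load the reductase catalog from a mapping or YAML file.

    With no argument, the shipped default catalog (17 types) is used.
    """
    if config is None:
        text = (
            resources.files("quinrec.data") / "reductase_catalog.yaml"
        ).read_text()
        config = yaml.safe_load(text)
    elif isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    catalog: dict[str, ReductaseType] = {}
    for name, entry in config.items():
        if name in catalog:
            raise ValueError(f"duplicate reductase type {name!r}")
        catalog[name] = ReductaseType(
            name,
            entry.get("acceptor", "unknown"),
            tuple(entry["subunits"]),
            frozenset(entry["quinones"]),
        )
    return catalog


def classify_codistribution(
    pattern: QuinonePattern,
    presence: Mapping[str, bool],
    catalog: Mapping[str, ReductaseType],
) -> CodistCall:
    """Four-way category for one genome, with quinone-compatibility conflicts.

    A reductase type counts as present when all its required subunit
    families are present.  The category depends only on (any reductase
    present, any quinone producible); conflicts list present reductases
    whose compatible quinones the genome cannot make.
    """
    present = tuple(
        name
        for name in sorted(catalog)
        if all(presence.get(f, False) for f in catalog[name].subunit_families)
    )
    has_reductase = bool(present)
    has_quinone = bool(pattern.quinones)
    if has_reductase and has_quinone:
        category = BOTH
    elif has_reductase:
        category = REDUCTASE_ONLY
    elif has_quinone:
        category = QUINONE_ONLY
    else:
        category = NEITHER
    conflicts = tuple(
        name
        for name in present
        if not (catalog[name].compatible_quinones & pattern.quinones)
    )
    return CodistCall(pattern.genome_id, category, present, conflicts)


def _pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (printed-table convention)."""
    value = Decimal(count) * 100 / Decimal(total)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def agreement_stats(calls: Iterable[CodistCall]) -> dict[str, object]:
    """Category counts, percentages and overall agreement.

    Agreement means the two repertoires concur: category ``both`` or
    ``neither``.  Percentages are of the genome total, half-up to one
    decimal.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("agreement_stats: no calls")
    total = len(calls)
    counts = {cat: sum(1 for c in calls if c.category == cat) for cat in CATEGORIES}
    agree = counts[BOTH] + counts[NEITHER]
    return {
        "n_genomes": total,
        "counts": counts,
        "percentages": {cat: _pct(n, total) for cat, n in counts.items()},
        "agreement_count": agree,
        "agreement_percent": _pct(agree, total),
        "disagreement_percent": _pct(total - agree, total),
    }


def calls_table(calls: Iterable[CodistCall]) -> pd.DataFrame:
    rows = [
        (c.genome_id, c.category, ",".join(c.present_reductases),
         ",".join(c.conflicts))
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["genome_id", "category", "reductases", "conflicts"]
    )
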