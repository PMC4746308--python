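"""Quinone biosynthesis pathway definitions and per-genome classification.

Three routes are modeled. The Ubi pathway makes ubiquinone (UQ) from
chorismate; the Men (O-succinylbenzoate) pathway makes demethylmenaquinone
(DMK) and, with the UbiE/MenG methyltransferase, menaquinone (MK); the Mqn
(futalosine) pathway reaches 1,4-dihydroxy-6-naphthoate in its long-known
part ("core") and continues to MK through the predicted late steps
MqnP (polyprenyltransferase), MqnL/MqnM (carboxy-lyases) and MenG
("extended" mode).

A pathway is *complete* in a genome when every role is covered by at least
one of its alternative gene-family forms, i.e. the known genes form an
uninterrupted route from chorismate; it is *absent* when no role is covered,
and *incomplete* otherwise (a single present gene already counts as
incomplete, not absent).

Role and form lists are configuration, not code: any roster can be supplied;
the classification rules are role-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

UBI, MEN, MQN_CORE, MQN_LATE = "Ubi", "Men", "Mqn_core", "Mqn_late"
MENG_FAMILY = "ubiE_menG"  # one family shared by the Ubi, Men and Mqn_late rosters
MENG_ROLE = "MenG"

COMPLETE, INCOMPLETE, ABSENT = "complete", "incomplete", "absent"
_STATUS_ORDER = {ABSENT: 0, INCOMPLETE: 1, COMPLETE: 2}


@dataclass(frozen=True)
class Role:
    role_name: str
    step_index: int
    alternative_forms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.alternative_forms:
            raise ValueError(f"role {self.role_name}: needs >=1 alternative form")


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    roles: tuple[Role, ...]
    mode: str = "legacy"

    def __post_init__(self) -> None:
        steps = [r.step_index for r in self.roles]
        if steps != sorted(steps) or len(steps) != len(set(steps)):
            raise ValueError(f"{self.pathway_id}: roles must have unique ordered steps")

    def role_names(self) -> list[str]:
        return [r.role_name for r in self.roles]


@dataclass(frozen=True)
class PathwayCall:
    genome_id: str
    pathway_id: str
    status: str
    present_roles: tuple[str, ...]
    missing_roles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.status == COMPLETE and self.missing_roles:
            raise ValueError("complete call with missing roles")
        if self.status == ABSENT and self.present_roles:
            raise ValueError("absent call with present roles")


@dataclass(frozen=True)
class QuinonePattern:
    genome_id: str
    quinones: frozenset[str]

    def __post_init__(self) -> None:
        if "MK" in self.quinones and "DMK" not in self.quinones:
            raise ValueError("MK implies DMK (DMK is the MK precursor)")


def _roles(*specs: tuple[str, Iterable[str]]) -> tuple[Role, ...]:
    return tuple(
        Role(name, i, frozenset(forms)) for i, (name, forms) in enumerate(specs)
    )


_LEGACY = {
    UBI: _roles(
        ("UbiC", ["ubiC"]),
        ("UbiA", ["ubiA"]),
        ("UbiD/UbiX", ["ubiD", "ubiX", "ubiZ"]),
        ("UbiB", ["ubiB"]),
        ("UbiH", ["ubiH"]),
        ("UbiE", [MENG_FAMILY]),
        ("UbiF", ["ubiF"]),
        ("UbiG", ["ubiG"]),
    ),
    MEN: _roles(
        ("MenF", ["menF"]),
        ("MenD", ["menD"]),
        ("MenH", ["menH", "menY"]),
        ("MenC", ["menC"]),
        ("MenE", ["menE"]),
        ("MenB", ["menB"]),
        ("MenI", ["menI", "menJ"]),
        ("MenA", ["menA"]),
        ("MenG", [MENG_FAMILY]),
    ),
    MQN_CORE: _roles(
        ("MqnA", ["mqnA"]),
        ("MqnE", ["mqnE"]),
        ("MqnB", ["mqnB"]),
        ("MqnC", ["mqnC"]),
        ("MqnD", ["mqnD", "mqnZ"]),
    ),
}

_MQN_LATE = _roles(
    ("MqnP", ["mqnP"]),
    ("MqnL", ["mqnL"]),
    ("MqnM", ["mqnM"]),
    ("MenG", [MENG_FAMILY]),
)


def default_definitions(mode: str = "legacy") -> list[PathwayDefinition]:
    """Built-in pathway rosters.

    ``legacy`` ships Ubi, Men and the Mqn core (stopping at
    1,4-dihydroxy-6-naphthoate, the long-known boundary of the futalosine
    route); ``extended`` adds the predicted Mqn late steps as a fourth
    definition. All rosters are overridable by constructing
    :class:`PathwayDefinition` objects directly or via config.
    """
    if mode not in {"legacy", "extended"}:
        raise ValueError(f"unknown mode {mode!r}")
    defs = [
        PathwayDefinition(pid, roles, mode) for pid, roles in _LEGACY.items()
    ]
    if mode == "extended":
        defs.append(PathwayDefinition(MQN_LATE, _MQN_LATE, mode))
    return defs


def definitions_from_config(config: Mapping) -> list[PathwayDefinition]:
    """Build definitions from a ``{pathway: [{role, forms}, ...]}`` mapping."""
    defs = []
    for pid, roles in config.items():
        specs = [(r["role"], r["forms"]) for r in roles]
        defs.append(PathwayDefinition(pid, _roles(*specs)))
    return defs


def classify_pathway(
    genome_id: str,
    presence: Mapping[str, bool],
    definition: PathwayDefinition,
) -> PathwayCall:
    """Completeness verdict for one genome and one pathway.

    A role is present iff any of its alternative family forms is present;
    families missing from ``presence`` are treated as absent.
    """
    present, missing = [], []
    for role in definition.roles:
        if any(presence.get(f, False) for f in role.alternative_forms):
            present.append(role.role_name)
        else:
            missing.append(role.role_name)
    if not missing:
        status = COMPLETE
    elif not present:
        status = ABSENT
    else:
        status = INCOMPLETE
    return PathwayCall(genome_id, definition.pathway_id, status,
                       tuple(present), tuple(missing))


def classify_prefix(
    genome_id: str, presence: Mapping[str, bool], definition: PathwayDefinition
) -> int:
    """Number of consecutive roles present from the chorismate end.

    Complements :func:`classify_pathway` for gap reporting: genomes keeping
    only the late steps (a recurrent real-data configuration) score 0 here
    while still being ``incomplete`` overall.
    """
    n = 0
    for role in definition.roles:
        if any(presence.get(f, False) for f in role.alternative_forms):
            n += 1
        else:
            break
    return n


def infer_quinone_pattern(
    ubi_call: PathwayCall,
    men_call: PathwayCall,
    mqn_call: PathwayCall,
    has_menG: bool,
) -> QuinonePattern:
    """Which quinones a genome can synthesize.

    UQ requires a complete Ubi pathway. DMK is an intermediate of both the
    Men and Mqn routes, so either complete pathway confers DMK; MK
    additionally requires the UbiE/MenG methyltransferase. Because UbiE is
    itself a Ubi role, a complete Ubi pathway without menG is contradictory
    input and raises.
    """
    quinones: set[str] = set()
    if ubi_call.status == COMPLETE:
        if not has_menG:
            raise ValueError(
                f"{ubi_call.genome_id}: Ubi complete but menG absent - "
                "UbiE/MenG is a Ubi role, input is inconsistent"
            )
        quinones.add("UQ")

    def dmk_capable(call: PathwayCall) -> bool:
        # methylation (MenG) is the MK/DMK branch point, not a DMK step:
        # a pathway missing only that role still reaches DMK
        return call.status == COMPLETE or set(call.missing_roles) == {MENG_ROLE}

    if dmk_capable(men_call) or dmk_capable(mqn_call):
        quinones.add("DMK")
        if has_menG:
            quinones.add("MK")
    return QuinonePattern(ubi_call.genome_id, frozenset(quinones))


def pattern_name(pattern: QuinonePattern) -> str:
    order = [q for q in ("UQ", "MK", "DMK") if q in pattern.quinones]
    return "+".join(order) if order else "none"


def pattern_census(patterns: Iterable[QuinonePattern]) -> pd.DataFrame:
    """Counts per quinone-synthesis pattern; total row equals genome count."""
    counts: dict[str, int] = {}
    total = 0
    for p in patterns:
        counts[pattern_name(p)] = counts.get(pattern_name(p), 0) + 1
        total += 1
    rows = sorted(counts.items()) + [("total", total)]
    return pd.DataFrame(rows, columns=["pattern", "n_genomes"])


def calls_table(calls: Iterable[PathwayCall]) -> pd.DataFrame:
    rows = [
        (c.genome_id, c.pathway_id, c.status,
         ",".join(c.present_roles), ",".join(c.missing_roles))
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["genome_id", "pathway_id", "status",
                       "present_roles", "missing_roles"]
    )
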