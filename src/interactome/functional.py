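"""Functional-profile comparisons: KO tables, module completeness, Venn.

A KEGG module is represented as an ordered list of "blocks", each block a
set of alternative KO identifiers (pre-flattened from the KEGG boolean
grammar: any one alternative satisfies the block).  A module counts as
complete when at most one block is missing — the "complete or nearly
complete (no more than one gene missing)" convention used when comparing a
host genome's pathway content with its microbiome's.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from skbio import DistanceMatrix

from .dissimilarity import (
    DecayFit,
    EARTH_RADIUS_KM,
    bray_curtis,
    distance_decay_glm,
    great_circle_distances,
)

__all__ = [
    "ModuleDef",
    "CompletenessResult",
    "parse_module_defs",
    "write_module_defs",
    "module_completeness",
    "complete_modules",
    "venn_partition",
    "read_ko_table",
    "write_ko_table",
    "ko_presence",
    "functional_decay",
]

KO_PATTERN = re.compile(r"^K\d+$")
MAX_MISSING_BLOCKS = 1


@dataclass(frozen=True)
class ModuleDef:
    """One module: an id and ordered blocks of alternative KOs."""

    module_id: str
    blocks: tuple[frozenset[str], ...]

    def __post_init__(self):
        if not self.blocks:
            raise ValueError(f"module {self.module_id!r} has no blocks")
        if any(len(b) == 0 for b in self.blocks):
            raise ValueError(f"module {self.module_id!r} has an empty block")


@dataclass(frozen=True)
class CompletenessResult:
    module_id: str
    blocks_total: int
    blocks_missing: int

    @property
    def complete(self) -> bool:
        return self.blocks_missing <= MAX_MISSING_BLOCKS


class ModuleParseError(ValueError):
    pass


def parse_module_defs(path) -> list[ModuleDef]:
    """Parse a module-definition file.

    One module per line: ``module_id<TAB>block block ...`` where a block is
    a comma-separated list of alternative KO ids, e.g.
    ``M1\tK00001 K00002,K00003 K00004``.
    """
    modules: list[ModuleDef] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                module_id, rest = line.split("\t", 1)
            except ValueError:
                raise ModuleParseError(f"line {lineno}: expected 'id<TAB>blocks'")
            module_id = module_id.strip()
            if module_id in seen:
                raise ModuleParseError(f"line {lineno}: duplicate module id {module_id!r}")
            seen.add(module_id)
            blocks = []
            for token in rest.split():
                alts = frozenset(a for a in token.split(",") if a)
                if not alts:
                    raise ModuleParseError(f"line {lineno}: empty block in {module_id!r}")
                blocks.append(alts)
            if not blocks:
                raise ModuleParseError(f"line {lineno}: module {module_id!r} has no blocks")
            modules.append(ModuleDef(module_id, tuple(blocks)))
    return modules


def write_module_defs(modules: Sequence[ModuleDef], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for m in modules:
            blocks = " ".join(",".join(sorted(b)) for b in m.blocks)
            fh.write(f"{m.module_id}\t{blocks}\n")


def module_completeness(present_kos: Iterable[str], module: ModuleDef) -> CompletenessResult:
    """Count missing blocks: a block is missing iff none of its alternatives
    is present.  Adding KOs can never increase ``blocks_missing``."""
    present = set(present_kos)
    missing = sum(1 for block in module.blocks if not (block & present))
    return CompletenessResult(module.module_id, len(module.blocks), missing)


def complete_modules(
    present_kos: Iterable[str], modules: Sequence[ModuleDef]
) -> set[str]:
    """Ids of modules complete (<=1 missing block) given a KO set."""
    present = set(present_kos)
    return {
        m.module_id for m in modules if module_completeness(present, m).complete
    }


def venn_partition(
    host_complete: Iterable[str], microbiome_complete: Iterable[str]
) -> dict[str, set[str]]:
    """Two-set partition of complete modules: host-only / shared / microbiome-only."""
    host = set(host_complete)
    micro = set(microbiome_complete)
    return {
        "host_only": host - micro,
        "shared": host & micro,
        "microbiome_only": micro - host,
    }


def read_ko_table(path) -> pd.DataFrame:
    """Read a KO-by-group abundance TSV into a groups x KOs DataFrame."""
    raw = pd.read_csv(path, sep="\t", header=0, index_col=0)
    if raw.index.duplicated().any():
        raise ValueError(f"{path}: duplicate KO id")
    bad = [k for k in raw.index.astype(str) if not KO_PATTERN.match(k)]
    if bad:
        raise ValueError(f"{path}: malformed KO id {bad[0]!r}")
    if (raw.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative abundance")
    table = raw.T
    table.index.name = "group"
    table.columns.name = "KO"
    return table


def write_ko_table(table: pd.DataFrame, path) -> None:
    out = table.T
    out.index.name = "KO"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        out.to_csv(fh, sep="\t", lineterminator="\n")


def ko_presence(table: pd.DataFrame, min_abundance: float = 0.0) -> set[str]:
    """KOs whose abundance pooled across groups exceeds ``min_abundance``."""
    pooled = table.sum(axis=0)
    return set(pooled.index[pooled > min_abundance].astype(str))


def functional_decay(
    ko_table_by_site: pd.DataFrame,
    geo: pd.DataFrame,
    radius_km: float = EARTH_RADIUS_KM,
) -> tuple[DecayFit, DistanceMatrix]:
    """Bray-Curtis on per-site KO abundance profiles, regressed on distance.

    ``ko_table_by_site`` is sites x KOs; site labels must match ``geo``.
    """
    sites = set(map(str, ko_table_by_site.index))
    if sites != set(map(str, geo.index)):
        raise ValueError(
            f"site labels differ between KO table and coordinates: "
            f"{sorted(sites ^ set(map(str, geo.index)))}"
        )
    dissim = bray_curtis(ko_table_by_site)
    dist = great_circle_distances(geo, radius_km=radius_km)
    return distance_decay_glm(dist, dissim), dissim
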