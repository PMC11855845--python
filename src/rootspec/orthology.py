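"""Conserved tissue-specific genes via orthogroup intersection.

Consumes orthogroup tables in the OrthoFinder v2 ``Orthogroups.tsv`` layout
(first column orthogroup id, one column per species, comma-separated gene
lists) and intersects them with per-species tissue-specific gene sets: a
focal-species gene is conserved when every required species contributes at
least one tissue-specific co-member of the same orthogroup.  Genes outside
every orthogroup carry no homology evidence and can never be conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "OrthogroupTable",
    "ConservedSet",
    "read_orthogroups",
    "write_orthogroups",
    "conserved_specific",
    "write_conserved_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class OrthogroupTable:
    """orthogroup id -> {species -> gene list}; each gene in <= 1 orthogroup."""

    species: list[str]
    members: dict[str, dict[str, list[str]]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for og, per_sp in self.members.items():
            for sp, genes in per_sp.items():
                if sp not in self.species:
                    raise ValueError(f"{og}: unknown species {sp!r}")
                for g in genes:
                    if g in seen:
                        raise ValueError(
                            f"gene {g!r} listed in both {seen[g]} and {og}"
                        )
                    seen[g] = og
        self._orthogroup_of = seen

    def orthogroup_of(self, gene: str) -> str | None:
        return self._orthogroup_of.get(gene)

    def genes(self, orthogroup: str, species: str) -> list[str]:
        return self.members[orthogroup].get(species, [])

    def all_genes(self) -> set[str]:
        return set(self._orthogroup_of)


@dataclass
class ConservedSet:
    """Focal-species tissue-specific genes conserved across required species."""

    focal_species: str
    required_species: frozenset[str]
    genes: list[str]
    per_gene_support: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    orthogroup_of: dict[str, str] = field(default_factory=dict)


def _parse_cell(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    text = str(cell).strip()
    if not text:
        return []
    return [g.strip() for g in text.split(",") if g.strip()]


def read_orthogroups(path: str | Path) -> OrthogroupTable:
    """Parse an ``Orthogroups.tsv`` file; header names the species columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need an orthogroup column plus >= 1 species column")
    og_col = df.columns[0]
    species = [str(c) for c in df.columns[1:]]
    members: dict[str, dict[str, list[str]]] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        og = str(row[0]).strip()
        if not og or og.lower() == "nan":
            raise ValueError(f"{path}:{line_no}: malformed row (missing orthogroup id)")
        if og in members:
            raise ValueError(f"{path}:{line_no}: duplicate orthogroup id {og!r}")
        per_sp = {sp: _parse_cell(cell) for sp, cell in zip(species, row[1:])}
        if not any(per_sp.values()):
            raise ValueError(f"{path}:{line_no}: orthogroup {og!r} has no members")
        members[og] = per_sp
    try:
        return OrthogroupTable(species=species, members=members)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_orthogroups(table: OrthogroupTable, path: str | Path) -> None:
    rows = [
        [og] + [", ".join(table.members[og].get(sp, [])) for sp in table.species]
        for og in table.members
    ]
    pd.DataFrame(rows, columns=["Orthogroup", *table.species]).to_csv(
        path, sep="\t", index=False
    )


def conserved_specific(
    specific_sets: Mapping[str, Iterable[str]],
    og: OrthogroupTable,
    focal: str,
    required: Iterable[str],
) -> ConservedSet:
    """Focal-species specific genes whose orthogroup has a tissue-specific
    co-member in every required species.

    ``specific_sets`` maps species label to its tissue-specific gene ids.
    With ``required`` empty the result is the focal specific genes that
    belong to any orthogroup.
    """
    required = frozenset(required)
    if focal in required:
        raise ValueError(f"focal species {focal!r} cannot also be required")
    for sp in {focal, *required}:
        if sp not in og.species:
            raise ValueError(f"species {sp!r} absent from orthogroup table {og.species}")
        if sp not in specific_sets:
            raise ValueError(f"no specific gene set supplied for species {sp!r}")
    sets = {sp: set(specific_sets[sp]) for sp in specific_sets}

    genes: list[str] = []
    support: dict[str, dict[str, list[str]]] = {}
    og_of: dict[str, str] = {}
    n_unassigned = 0
    for gene in sorted(sets[focal]):
        grp = og.orthogroup_of(gene)
        if grp is None:
            n_unassigned += 1
            continue
        witnesses = {}
        ok = True
        for sp in sorted(required):
            w = [g for g in og.genes(grp, sp) if g in sets[sp]]
            if not w:
                ok = False
                break
            witnesses[sp] = w
        if ok:
            genes.append(gene)
            support[gene] = witnesses
            og_of[gene] = grp
    if n_unassigned:
        logger.info(
            "%d %s-specific gene(s) not assigned to any orthogroup were dropped",
            n_unassigned, focal,
        )
    return ConservedSet(
        focal_species=focal,
        required_species=required,
        genes=genes,
        per_gene_support=support,
        orthogroup_of=og_of,
    )


def write_conserved_tsv(cs: ConservedSet, path: str | Path) -> None:
    rows = []
    for g in cs.genes:
        witnesses = ";".join(
            f"{sp}={','.join(ws)}" for sp, ws in sorted(cs.per_gene_support[g].items())
        )
        rows.append((g, cs.orthogroup_of.get(g, ""), witnesses))
    pd.DataFrame(rows, columns=["gene_id", "orthogroup_id", "witnesses"]).to_csv(
        path, sep="\t", index=False
    )
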