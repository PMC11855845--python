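"""De novo motif discovery and cross-tool core consensus.

Three stages live here:

* an enumerative over-representation scan (``enumerate_enriched_kmers``)
  that compares foreground promoters (e.g. root-specific genes) against a
  background set (e.g. embryo- or endosperm-specific genes) at the gene
  level, using a one-sided hypergeometric test with Benjamini-Hochberg
  correction within each k;
* readers for external discovery-tool reports (MEME minimal motif format
  and plain consensus-string lists);
* "sequence continuity truncation" of reported motifs into unambiguous
  6-9 bp cores, followed by a cross-tool consensus that keeps cores found
  by at least ``min_tools`` distinct tools and classifies each core by the
  backgrounds under which it was recovered (``**`` both embryo and
  endosperm for at least one tool, ``*`` exactly one, ``NA`` neither).

K-mers and cores are reverse-complement canonicalized throughout (the
lexicographically smaller of a string and its reverse complement), so
both-strand occurrences of one element are counted once.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._sequence import IUPAC_FOR_BASES, UNAMBIGUOUS, canonical, unambiguous_runs
from .promoters import PromoterSet

__all__ = [
    "MotifReport",
    "MotifCore",
    "KmerEnrichment",
    "enumerate_enriched_kmers",
    "parse_motif_report",
    "truncate_to_cores",
    "consensus_cores",
    "cores_to_frame",
    "write_cores_tsv",
]

logger = logging.getLogger(__name__)

BACKGROUNDS = ("embryo", "endosperm", "none")


@dataclass(frozen=True)
class ReportedMotif:
    consensus: str
    score: float
    rank: int


@dataclass
class MotifReport:
    """Motifs reported by one tool run against one background."""

    tool: str
    background: str  # "embryo" | "endosperm" | "none"
    motifs: list[ReportedMotif]

    def __post_init__(self) -> None:
        if self.background not in BACKGROUNDS:
            raise ValueError(f"background must be one of {BACKGROUNDS}")
        ranks = [m.rank for m in self.motifs]
        if len(set(ranks)) != len(ranks):
            raise ValueError("duplicate motif ranks within a report")
        for m in self.motifs:
            if len(m.consensus) < 4:
                raise ValueError(f"motif consensus too short: {m.consensus!r}")


@dataclass
class MotifCore:
    """A 6-9 bp unambiguous core with its cross-tool/background support."""

    sequence: str
    species: str = ""
    support: dict[tuple[str, str], bool] = field(default_factory=dict)
    star_class: str = "NA"  # "NA" | "*" | "**"
    weeder_flag: bool = False
    per_tool_star: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 6 <= len(self.sequence) <= 9:
            raise ValueError("core length must be 6-9 bp")

    @property
    def n_tools(self) -> int:
        return len({tool for (tool, _bg), present in self.support.items() if present})


@dataclass(frozen=True)
class KmerEnrichment:
    kmer: str
    fg_genes_with: int
    fg_total: int
    bg_genes_with: int
    bg_total: int
    p_value: float
    q_value: float

    @property
    def fg_fraction(self) -> float:
        return self.fg_genes_with / self.fg_total


def _gene_kmer_sets(pset: PromoterSet, k: int) -> dict[str, frozenset[str]]:
    """Canonical k-mers present in each promoter; windows containing a
    non-ACGT symbol (N etc.) contribute nothing."""
    out = {}
    skipped = 0
    for rec in pset:
        seq = rec.sequence
        if len(seq) < k:
            skipped += 1
            out[rec.gene_id] = frozenset()
            continue
        kmers = set()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if set(w) <= UNAMBIGUOUS:
                kmers.add(canonical(w))
        out[rec.gene_id] = frozenset(kmers)
    if skipped:
        logger.info("%d promoter(s) shorter than k=%d contributed no k-mers", skipped, k)
    return out


def enumerate_enriched_kmers(
    fg: PromoterSet,
    bg: PromoterSet,
    k_range: Iterable[int] = range(6, 10),
    top: int | None = 100,
) -> list[KmerEnrichment]:
    """Rank canonical k-mers by gene-level over-representation in ``fg``.

    For each k and each k-mer seen in at least one foreground promoter
    (either strand), genes containing it are counted in foreground and
    background and a one-sided hypergeometric enrichment p-value computed
    over the pooled gene universe; q-values are Benjamini-Hochberg within
    each k.  Results are ordered by ascending p, then descending foreground
    fraction, then k-mer; ``top`` limits the list per k (None keeps all).
    """
    if len(fg) == 0 or len(bg) == 0:
        raise ValueError("foreground and background promoter sets must be non-empty")
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 4 or k > 12 for k in ks):
        raise ValueError("k must lie in 4..12")

    results: list[KmerEnrichment] = []
    fg_total, bg_total = len(fg), len(bg)
    M = fg_total + bg_total
    for k in ks:
        fg_sets = _gene_kmer_sets(fg, k)
        bg_sets = _gene_kmer_sets(bg, k)
        candidates = sorted(set().union(*fg_sets.values())) if fg_sets else []
        if not candidates:
            continue
        fg_counts = np.array(
            [sum(km in s for s in fg_sets.values()) for km in candidates]
        )
        bg_counts = np.array(
            [sum(km in s for s in bg_sets.values()) for km in candidates]
        )
        # P(X >= fg_count) drawing fg_total genes from the pooled universe
        pvals = hypergeom.sf(fg_counts - 1, M, fg_counts + bg_counts, fg_total)
        pvals = np.clip(pvals, 0.0, 1.0)
        qvals = multipletests(pvals, method="fdr_bh")[1]
        per_k = [
            KmerEnrichment(
                kmer=km,
                fg_genes_with=int(fc),
                fg_total=fg_total,
                bg_genes_with=int(bc),
                bg_total=bg_total,
                p_value=float(p),
                q_value=float(q),
            )
            for km, fc, bc, p, q in zip(candidates, fg_counts, bg_counts, pvals, qvals)
        ]
        per_k.sort(key=lambda e: (e.p_value, -e.fg_fraction, e.kmer))
        results.extend(per_k if top is None else per_k[:top])
    return results


def enrichment_to_report(
    enrichments: Sequence[KmerEnrichment],
    tool: str = "rootspec-enum",
    background: str = "none",
    max_q: float | None = 0.05,
) -> MotifReport:
    """Package enumerator output as a MotifReport for the consensus stage."""
    kept = [e for e in enrichments if max_q is None or e.q_value <= max_q]
    motifs = [
        ReportedMotif(consensus=e.kmer, score=-math.log10(max(e.p_value, 1e-300)), rank=i + 1)
        for i, e in enumerate(kept)
    ]
    return MotifReport(tool=tool, background=background, motifs=motifs)


# ---------------------------------------------------------------------------
# external report parsing


def _consensus_from_pwm(pwm: np.ndarray) -> str:
    """Highest-probability base per column; columns whose maximum is below
    0.6 are rendered as the IUPAC ambiguity of all bases with p >= 0.25."""
    bases = "ACGT"
    out = []
    for col in pwm:
        imax = int(np.argmax(col))
        if col[imax] >= 0.6:
            out.append(bases[imax])
        else:
            members = frozenset(b for b, p in zip(bases, col) if p >= 0.25)
            if not members:
                members = frozenset(bases[imax])
            out.append(IUPAC_FOR_BASES[members])
    return "".join(out)


def _parse_meme_minimal(path: str | Path) -> list[ReportedMotif]:
    motifs = []
    name = None
    pwm_rows: list[list[float]] = []
    expecting = 0

    def flush():
        nonlocal name, pwm_rows
        if name is not None and pwm_rows:
            pwm = np.asarray(pwm_rows, dtype=float)
            sums = pwm.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-3):
                raise ValueError(
                    f"{path}: PWM rows of motif {name!r} do not sum to 1 (±1e-3)"
                )
            motifs.append(
                ReportedMotif(
                    consensus=_consensus_from_pwm(pwm), score=0.0, rank=len(motifs) + 1
                )
            )
        name, pwm_rows = None, []

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("MOTIF"):
                flush()
                parts = line.split()
                name = parts[1] if len(parts) > 1 else f"motif{len(motifs)+1}"
                expecting = 0
            elif line.startswith("letter-probability matrix"):
                expecting = 1
                pwm_rows = []
            elif expecting and line and (line[0].isdigit() or line[0] == "."):
                pwm_rows.append([float(v) for v in line.split()])
            elif expecting and not line:
                expecting = 0
    flush()
    if not motifs:
        raise ValueError(f"{path}: no motifs found in MEME-minimal file")
    return motifs


def _parse_consensus_list(path: str | Path) -> list[ReportedMotif]:
    motifs = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            motifs.append(ReportedMotif(consensus=s.upper(), score=0.0, rank=len(motifs) + 1))
    if not motifs:
        raise ValueError(f"{path}: empty consensus list")
    return motifs


def parse_motif_report(
    path: str | Path,
    dialect: str,
    tool: str,
    background: str = "none",
) -> MotifReport:
    """Read a discovery-tool report (``meme_minimal`` or ``consensus_list``)."""
    if dialect == "meme_minimal":
        motifs = _parse_meme_minimal(path)
    elif dialect == "consensus_list":
        motifs = _parse_consensus_list(path)
    else:
        raise ValueError(f"unknown report dialect {dialect!r}")
    return MotifReport(tool=tool, background=background, motifs=motifs)


# ---------------------------------------------------------------------------
# core truncation + consensus


def truncate_to_cores(
    report: MotifReport, len_range: Iterable[int] = range(6, 10)
) -> set[str]:
    """Unambiguous 6-9 bp cores of every motif in a report.

    Each reported consensus is split at ambiguous IUPAC positions
    (continuity truncation); every contiguous A/C/G/T substring with length
    in ``len_range`` becomes a candidate core.  Cores are deduplicated and
    reverse-complement canonicalized within the report.
    """
    lens = sorted(set(int(x) for x in len_range))
    cores: set[str] = set()
    for m in report.motifs:
        for run in unambiguous_runs(m.consensus):
            for k in lens:
                for i in range(len(run) - k + 1):
                    cores.add(canonical(run[i : i + k]))
    return cores


def truncate_reports_to_cores(
    reports: Sequence[MotifReport], len_range: Iterable[int] = range(6, 10)
) -> dict[tuple[str, str], set[str]]:
    """Per-(tool, background) core sets for :func:`consensus_cores`."""
    out: dict[tuple[str, str], set[str]] = {}
    for rep in reports:
        key = (rep.tool, rep.background)
        out.setdefault(key, set()).update(truncate_to_cores(rep, len_range))
    return out


def consensus_cores(
    per_report_cores: Mapping[tuple[str, str], set[str]],
    min_tools: int = 2,
    species: str = "",
) -> list[MotifCore]:
    """Cores supported by >= ``min_tools`` distinct tools, star-classified.

    Background runs of the same tool count once toward the tool tally.  For
    every background-dependent tool the star class records whether the core
    was recovered under both the embryo and endosperm backgrounds (``**``),
    exactly one (``*``) or neither (``NA``); a core's overall class is the
    strongest per-tool class.  ``weeder_flag`` marks presence in any
    background-free run.
    """
    tools = {tool for tool, _bg in per_report_cores}
    if len(tools) < 2:
        raise ValueError("consensus requires reports from >= 2 distinct tools")

    all_cores: set[str] = set()
    for cores in per_report_cores.values():
        all_cores.update(cores)

    out: list[MotifCore] = []
    for core in sorted(all_cores):
        support = {key: core in cores for key, cores in per_report_cores.items()}
        supporting_tools = {tool for (tool, _bg), p in support.items() if p}
        if len(supporting_tools) < min_tools:
            continue
        per_tool_star: dict[str, str] = {}
        for tool in sorted(tools):
            bgs = {
                bg
                for (t, bg), p in support.items()
                if p and t == tool and bg in ("embryo", "endosperm")
            }
            per_tool_star[tool] = {0: "NA", 1: "*", 2: "**"}[len(bgs)]
        if "**" in per_tool_star.values():
            star = "**"
        elif "*" in per_tool_star.values():
            star = "*"
        else:
            star = "NA"
        weeder = any(
            p for (t, bg), p in support.items() if p and bg == "none"
        )
        out.append(
            MotifCore(
                sequence=core,
                species=species,
                support=support,
                star_class=star,
                weeder_flag=weeder,
                per_tool_star=per_tool_star,
            )
        )
    return out


def cores_to_frame(cores: Sequence[MotifCore]) -> pd.DataFrame:
    """Table-style summary: one row per core, one star column per tool."""
    tools = sorted({t for c in cores for t in c.per_tool_star})
    rows = []
    for c in cores:
        row = {
            "sequence": c.sequence,
            "length": len(c.sequence),
            "species": c.species,
            "n_tools": c.n_tools,
            "star_class": c.star_class,
            "weeder": "Y" if c.weeder_flag else "NA",
        }
        for t in tools:
            row[t] = c.per_tool_star.get(t, "NA")
        rows.append(row)
    return pd.DataFrame(rows)


def write_cores_tsv(cores: Sequence[MotifCore], path: str | Path) -> None:
    cores_to_frame(cores).to_csv(path, sep="\t", index=False)
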