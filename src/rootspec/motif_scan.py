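"""Exact motif scanning, the frequency-of-occurrence statistic, and
positional profiles.

Scanning is exact string matching of unambiguous ACGT cores against
promoter sequences, counting overlapping sites.  Both strands are searched
by default: reverse-strand sites are found by matching the reverse
complement of the motif on the stored (promoter 5'->3') sequence; a
palindromic motif's site is reported once, on the + strand.  Ns in the
sequence never match.

The frequency of occurrence of a motif in a gene set is the percentage of
genes whose promoter contains at least one site,

    frequency = 100 * genes_with_motif / genes_total,

a presence/absence statistic that is insensitive to repeated sites within
one promoter.  An optional Fisher exact test compares the statistic
between two gene sets, with Benjamini-Hochberg correction across motifs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from ._sequence import is_palindromic, revcomp, validate_motif
from .promoters import PromoterSet

__all__ = [
    "OccurrenceRecord",
    "FrequencyTable",
    "scan",
    "frequency",
    "positional_profile",
    "compare_frequencies",
    "occurrences_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OccurrenceRecord:
    """Sites of one motif in one promoter.

    ``positions`` holds (offset, strand) pairs; the offset is the 0-based
    start of the site from the promoter 5' end on the stored sequence.
    """

    gene_id: str
    motif: str
    positions: tuple[tuple[int, str], ...]
    promoter_length: int

    @property
    def count(self) -> int:
        return len(self.positions)


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (overlapping) match offsets of needle in haystack."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def scan(
    promoters: PromoterSet,
    motifs: Sequence[str],
    strands: str = "both",
) -> list[OccurrenceRecord]:
    """Exact occurrences of each motif core in each promoter.

    ``strands`` is ``"both"`` (default) or ``"forward"``.  Overlapping
    matches are all reported.  Records are emitted for every
    (gene, motif) pair, including zero-count ones, so downstream
    statistics see the full denominator.
    """
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    motifs = [validate_motif(m) for m in motifs]
    out: list[OccurrenceRecord] = []
    for rec in promoters:
        seq = rec.sequence
        for m in motifs:
            positions = [(i, "+") for i in _find_all(seq, m)]
            if strands == "both" and not is_palindromic(m):
                positions += [(i, "-") for i in _find_all(seq, revcomp(m))]
            positions.sort()
            out.append(
                OccurrenceRecord(
                    gene_id=rec.gene_id,
                    motif=m,
                    positions=tuple(positions),
                    promoter_length=len(seq),
                )
            )
    return out


@dataclass
class FrequencyTable:
    rows: pd.DataFrame  # motif, set_label, genes_with_motif, genes_total, frequency_percent

    def get(self, motif: str, set_label: str) -> float:
        sel = self.rows[(self.rows.motif == motif) & (self.rows.set_label == set_label)]
        if sel.empty:
            raise KeyError((motif, set_label))
        return float(sel.frequency_percent.iloc[0])

    def write_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def frequency(
    occurrences: Sequence[OccurrenceRecord],
    gene_sets: Mapping[str, Iterable[str]],
) -> FrequencyTable:
    """Percentage of genes in each set whose promoter contains each motif.

    Genes of a set without a promoter/occurrence record still count in the
    denominator (logged); duplicate sites within a gene do not inflate the
    statistic.
    """
    sets = {label: set(genes) for label, genes in gene_sets.items()}
    if not sets or any(len(s) == 0 for s in sets.values()):
        raise ValueError("gene sets must be non-empty")
    motifs = sorted({o.motif for o in occurrences})
    present: dict[str, set[str]] = {m: set() for m in motifs}
    covered: set[str] = set()
    for o in occurrences:
        covered.add(o.gene_id)
        if o.count > 0:
            present[o.motif].add(o.gene_id)
    rows = []
    for label, genes in sets.items():
        missing = genes - covered
        if missing:
            logger.info(
                "set %r: %d gene(s) lack a promoter record; kept in denominator",
                label, len(missing),
            )
        for m in motifs:
            with_m = len(genes & present[m])
            rows.append((m, label, with_m, len(genes), 100.0 * with_m / len(genes)))
    return FrequencyTable(
        rows=pd.DataFrame(
            rows,
            columns=["motif", "set_label", "genes_with_motif", "genes_total",
                     "frequency_percent"],
        )
    )


def positional_profile(
    occurrences: Sequence[OccurrenceRecord], bin_bp: int
) -> pd.DataFrame:
    """Histogram of site positions relative to the ATG.

    Each site is placed at the offset of its 3'-most base counted backwards
    from the translation start (ATG = 0), so a site abutting the ATG sits
    at -1 and falls in the bin [-bin_bp, 0).  Returns a DataFrame with
    ``bin_start``, ``bin_end`` (half-open, ATG-relative) and ``count``.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be > 0")
    rel = []
    max_len = 0
    for o in occurrences:
        max_len = max(max_len, o.promoter_length)
        for offset, _strand in o.positions:
            # last base of the site, ATG-relative (promoter 3' end abuts ATG)
            rel.append(offset + len(o.motif) - 1 - o.promoter_length)
    n_bins = max(1, int(np.ceil(max_len / bin_bp))) if max_len else 1
    edges = np.arange(-n_bins * bin_bp, 1, bin_bp)
    counts, _ = np.histogram(rel, bins=edges) if rel else (np.zeros(len(edges) - 1, int), edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1].astype(int), "bin_end": edges[1:].astype(int),
         "count": counts.astype(int)}
    )


def compare_frequencies(
    occurrences: Sequence[OccurrenceRecord],
    set_a: Iterable[str],
    set_b: Iterable[str],
    labels: tuple[str, str] = ("foreground", "background"),
) -> pd.DataFrame:
    """Per-motif Fisher exact test of presence/absence between two gene
    sets, BH-corrected across motifs.  Returns one row per motif with both
    frequencies, the odds ratio, p and q."""
    a, b = set(set_a), set(set_b)
    table = frequency(occurrences, {labels[0]: a, labels[1]: b}).rows
    motifs = sorted(table.motif.unique())
    rows = []
    for m in motifs:
        ra = table[(table.motif == m) & (table.set_label == labels[0])].iloc[0]
        rb = table[(table.motif == m) & (table.set_label == labels[1])].iloc[0]
        contingency = [
            [int(ra.genes_with_motif), int(ra.genes_total - ra.genes_with_motif)],
            [int(rb.genes_with_motif), int(rb.genes_total - rb.genes_with_motif)],
        ]
        odds, p = fisher_exact(contingency, alternative="greater")
        rows.append(
            (m, ra.frequency_percent, rb.frequency_percent, odds, p)
        )
    df = pd.DataFrame(
        rows, columns=["motif", f"freq_{labels[0]}", f"freq_{labels[1]}",
                       "odds_ratio", "p_value"]
    )
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def occurrences_to_frame(occurrences: Sequence[OccurrenceRecord]) -> pd.DataFrame:
    """BED-like flat table of sites (gene-relative coordinates)."""
    rows = []
    for o in occurrences:
        for offset, strand in o.positions:
            rows.append((o.gene_id, offset, offset + len(o.motif), o.motif, strand))
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "motif", "strand"])
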