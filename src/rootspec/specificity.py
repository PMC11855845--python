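"""Modified tissue-specificity index (tau) and tissue-specific gene screening.

The index is computed on log-scaled expression,

    tau = sum_i (1 - x_hat_i) / (N - 1),   x_hat_i = log10(x_i + 1) / log10(xmax + 1),

where x_i is the aggregated TPM of the gene in tissue i of N and xmax its
maximum.  tau is 0 for uniform expression and 1 when expression is confined
to a single tissue; it is undefined for all-zero genes (log10(xmax+1) = 0).

A gene is called tissue-specific when tau exceeds a threshold (0.85 by
default) AND one of three ratio rules holds, guarding tau against extreme
xmax/xsec configurations:

    1. xsec != 0, 2 < xmax <= 20 and xmax / xsec >= 4
    2. xsec != 0, xmax > 20      and xmax / xsec >= 10
    3. xsec  = 0, xmax >= 1

Genes with 0 < xmax <= 2 and a non-zero second tissue satisfy no rule and
fail screening.  All comparisons are exact double-precision comparisons with
the printed bounds; ratios use raw aggregated TPM (the log applies only
inside x_hat).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import TissueProfile

__all__ = [
    "ScreeningThresholds",
    "SpecificityResult",
    "tau",
    "classic_tau",
    "screen",
    "screen_all",
    "call_tissue_genes",
    "specific_gene_set",
    "results_to_frame",
    "write_results_tsv",
]


@dataclass(frozen=True)
class ScreeningThresholds:
    """Screening constants; defaults are the published values."""

    tau_min: float = 0.85
    low_xmax_lo: float = 2.0    # rule 1 applies when low_xmax_lo < xmax <= low_xmax_hi
    low_xmax_hi: float = 20.0
    low_ratio: float = 4.0      # xmax/xsec bound under rule 1
    high_ratio: float = 10.0    # xmax/xsec bound under rule 2 (xmax > low_xmax_hi)
    solo_xmax_min: float = 1.0  # rule 3: xsec == 0 and xmax >= solo_xmax_min


DEFAULT_THRESHOLDS = ScreeningThresholds()


@dataclass(frozen=True)
class SpecificityResult:
    """Per-gene screening outcome.

    ``tau`` is ``nan`` when undefined (all-zero gene).  ``criterion`` is 1,
    2 or 3 for the matching rule, 0 for none.
    """

    gene_id: str
    tau: float
    xmax: float
    xsec: float
    max_tissue: str
    criterion: int
    is_specific: bool


def tau(profile: TissueProfile | Sequence[float]) -> float:
    """Tissue-specificity index in [0, 1]; ``nan`` when all values are zero.

    Accepts a :class:`TissueProfile` or a bare sequence of per-tissue
    values (N >= 2, all >= 0).
    """
    x = profile.values if isinstance(profile, TissueProfile) else np.asarray(profile, float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs >= 2 tissue values")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("tissue values must be finite and >= 0")
    xmax = float(x.max())
    denom = math.log10(xmax + 1.0)
    if denom == 0.0:  # all-zero gene (or xmax below double-precision resolution)
        return math.nan
    xhat = np.log10(x + 1.0) / denom
    return float(np.sum(1.0 - xhat) / (x.size - 1))


def classic_tau(profile: TissueProfile | Sequence[float]) -> float:
    """Original (linear-scale) index: x_hat_i = x_i / xmax.  Comparison mode only."""
    x = profile.values if isinstance(profile, TissueProfile) else np.asarray(profile, float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs >= 2 tissue values")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("tissue values must be finite and >= 0")
    xmax = float(x.max())
    if xmax == 0.0:
        return math.nan
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def _top_two(profile: TissueProfile) -> tuple[float, float, str]:
    """(xmax, xsec, max_tissue); ties for the maximum give xsec == xmax and
    the lexicographically first tied tissue as max_tissue."""
    x = profile.values
    tissues = profile.tissues
    xmax = float(x.max())
    tied = [t for t, v in zip(tissues, x) if v == xmax]
    max_tissue = min(tied)
    if len(tied) > 1:
        return xmax, xmax, max_tissue
    # exactly one maximal tissue here; xsec = largest of the remaining values
    others = np.delete(x, int(np.argmax(x)))
    xsec = float(others.max())
    return xmax, xsec, max_tissue


def _criterion(xmax: float, xsec: float, th: ScreeningThresholds) -> int:
    if xsec != 0.0:
        if th.low_xmax_lo < xmax <= th.low_xmax_hi and xmax / xsec >= th.low_ratio:
            return 1
        if xmax > th.low_xmax_hi and xmax / xsec >= th.high_ratio:
            return 2
        return 0
    return 3 if xmax >= th.solo_xmax_min else 0


def screen(
    profile: TissueProfile, thresholds: ScreeningThresholds = DEFAULT_THRESHOLDS
) -> SpecificityResult:
    """Apply the tau threshold and the three ratio rules to one gene."""
    t = tau(profile)
    xmax, xsec, max_tissue = _top_two(profile)
    crit = _criterion(xmax, xsec, thresholds)
    is_specific = (not math.isnan(t)) and t > thresholds.tau_min and crit != 0
    return SpecificityResult(
        gene_id=profile.gene_id,
        tau=t,
        xmax=xmax,
        xsec=xsec,
        max_tissue=max_tissue,
        criterion=crit,
        is_specific=is_specific,
    )


def screen_all(
    profiles: Iterable[TissueProfile],
    thresholds: ScreeningThresholds = DEFAULT_THRESHOLDS,
) -> list[SpecificityResult]:
    return [screen(p, thresholds) for p in profiles]


def call_tissue_genes(
    profiles: Sequence[TissueProfile],
    tissue: str,
    thresholds: ScreeningThresholds = DEFAULT_THRESHOLDS,
) -> list[SpecificityResult]:
    """Specific genes of one tissue, sorted by descending tau then gene id."""
    known = set()
    for p in profiles:
        known.update(p.tissues)
    if tissue not in known:
        raise ValueError(f"unknown tissue label {tissue!r}; tissues: {sorted(known)}")
    hits = [
        r
        for r in screen_all(profiles, thresholds)
        if r.is_specific and r.max_tissue == tissue
    ]
    hits.sort(key=lambda r: (-r.tau, r.gene_id))
    return hits


def specific_gene_set(
    profiles: Sequence[TissueProfile],
    tissue: str,
    thresholds: ScreeningThresholds = DEFAULT_THRESHOLDS,
) -> set[str]:
    return {r.gene_id for r in call_tissue_genes(profiles, tissue, thresholds)}


def results_to_frame(results: Iterable[SpecificityResult]) -> pd.DataFrame:
    rows = [
        (r.gene_id, r.tau, r.xmax, r.xsec, r.max_tissue, r.criterion, r.is_specific)
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "tau", "xmax", "xsec", "max_tissue", "criterion", "is_specific"],
    )


def write_results_tsv(results: Iterable[SpecificityResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
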