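"""Reading, validation and replicate aggregation of multi-tissue TPM matrices.

The pipeline starts from a genes x samples matrix of TPM values plus a
sample -> tissue assignment.  Replicates of a tissue are collapsed to one
value per tissue (mean by default) before the specificity index is
computed; TPM values are used raw, with no re-normalization across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TissueProfile",
    "read_expression_tsv",
    "read_tissue_map",
    "aggregate_replicates",
    "write_tissue_matrix",
]

AggMethod = Literal["mean", "median"]


@dataclass(frozen=True)
class TissueProfile:
    """Aggregated TPM of one gene across tissues, in a fixed tissue order."""

    gene_id: str
    tissue_values: dict[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        if len(self.tissue_values) < 2:
            raise ValueError(
                f"{self.gene_id}: specificity analysis needs >= 2 tissues, "
                f"got {len(self.tissue_values)}"
            )
        vals = np.asarray(list(self.tissue_values.values()), dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError(f"{self.gene_id}: tissue values must be finite and >= 0")

    @property
    def n_tissues(self) -> int:
        return len(self.tissue_values)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(list(self.tissue_values.values()), dtype=float)

    @property
    def tissues(self) -> list[str]:
        return list(self.tissue_values)


class ExpressionMatrix:
    """Validated genes x samples TPM matrix with a sample -> tissue map.

    Parameters
    ----------
    values
        genes x samples DataFrame of non-negative finite TPM values; the
        index holds gene ids, the columns sample ids.
    tissue_of_sample
        Mapping from every sample id to its tissue label.  At least two
        distinct tissues are required.
    """

    def __init__(self, values: pd.DataFrame, tissue_of_sample: Mapping[str, str]):
        values = values.astype(float)
        if values.empty:
            raise ValueError("empty expression matrix")
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression matrix contains non-finite values")
        if (arr < 0).any():
            raise ValueError("expression matrix contains negative TPM values")
        missing = [s for s in values.columns if s not in tissue_of_sample]
        if missing:
            raise ValueError(f"samples without tissue assignment: {missing}")
        self.values = values
        self.tissue_of_sample = {s: str(tissue_of_sample[s]) for s in values.columns}
        if len(set(self.tissue_of_sample.values())) < 2:
            raise ValueError("need >= 2 distinct tissues for specificity analysis")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tissues(self) -> list[str]:
        """Distinct tissue labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.tissue_of_sample[s], None)
        return list(seen)

    def samples_of_tissue(self, tissue: str) -> list[str]:
        return [s for s in self.values.columns if self.tissue_of_sample[s] == tissue]

    def write_tsv(self, path: str | Path, tissue_map_path: str | Path | None = None) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")
        if tissue_map_path is not None:
            pd.Series(self.tissue_of_sample, name="tissue").rename_axis("sample").to_csv(
                tissue_map_path, sep="\t", header=False
            )


def read_tissue_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample<TAB>tissue`` file (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "tissue"], dtype=str)
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in tissue map")
    return dict(zip(df["sample"], df["tissue"]))


def read_expression_tsv(
    path: str | Path, tissue_map: Mapping[str, str] | str | Path
) -> ExpressionMatrix:
    """Read a TSV expression matrix (gene rows, sample columns).

    ``tissue_map`` is either an in-memory mapping or the path of a
    ``sample<TAB>tissue`` sidecar file.  Non-numeric or negative cells are
    errors, as are duplicate gene ids and unassigned samples.
    """
    if isinstance(tissue_map, (str, Path)):
        tissue_map = read_tissue_map(tissue_map)
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionMatrix(df, tissue_map)


def aggregate_tissue_matrix(m: ExpressionMatrix, method: AggMethod = "mean") -> pd.DataFrame:
    """Genes x tissues DataFrame of replicate-aggregated TPM."""
    if method not in ("mean", "median"):
        raise ValueError(f"unknown aggregation method {method!r}")
    cols = {}
    for tissue in m.tissues:
        samples = m.samples_of_tissue(tissue)
        if not samples:  # unreachable via constructor, kept as a guard
            raise ValueError(f"tissue {tissue!r} has no samples")
        block = m.values[samples]
        cols[tissue] = block.mean(axis=1) if method == "mean" else block.median(axis=1)
    return pd.DataFrame(cols, index=m.values.index)


def aggregate_replicates(m: ExpressionMatrix, method: AggMethod = "mean") -> list[TissueProfile]:
    """One :class:`TissueProfile` per gene; tissue order is fixed across genes."""
    agg = aggregate_tissue_matrix(m, method)
    tissues = list(agg.columns)
    return [
        TissueProfile(gene_id=str(g), tissue_values=dict(zip(tissues, row)))
        for g, row in zip(agg.index, agg.to_numpy())
    ]


def write_tissue_matrix(profiles: Iterable[TissueProfile], path: str | Path) -> None:
    """Write aggregated tissue-level TPM as TSV (genes x tissues)."""
    profiles = list(profiles)
    df = pd.DataFrame(
        [p.tissue_values for p in profiles], index=[p.gene_id for p in profiles]
    )
    df.to_csv(path, sep="\t", index_label="gene_id")
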