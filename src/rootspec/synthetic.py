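"""Synthetic data generators with the statistical structure the pipeline assumes.

Every generator takes an explicit integer seed (or an existing
``numpy.random.Generator``) and is bit-reproducible; truth tables record
exactly what was planted so downstream sensitivity/specificity can be
computed without ambiguity.

The expression generator emulates a 13-tissue multi-replicate TPM matrix:
background genes draw a log-normal baseline shared across tissues with
mild per-tissue wobble and replicate noise, while planted tissue-specific
genes receive a high target-tissue value and near-zero leak elsewhere,
constructed so that the intended screening rule holds after replicate
aggregation.  The promoter generator emits i.i.d.- or Markov-1-composed
sequences with motif cores overwritten at drawn positions.  The orthogroup
generator builds tables in which a chosen fraction of orthogroups carry a
tissue-specific member in every species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._sequence import revcomp, validate_motif
from .expression import ExpressionMatrix
from .orthology import OrthogroupTable
from .promoters import PromoterRecord, PromoterSet

__all__ = [
    "DEFAULT_TISSUES",
    "PlantedGroup",
    "ExpressionSimSpec",
    "simulate_expression",
    "PlantedMotif",
    "PromoterSimSpec",
    "simulate_promoters",
    "OrthologySimSpec",
    "simulate_orthogroups",
]

#: The 13 tissues profiled, vegetative through reproductive.
DEFAULT_TISSUES = (
    "root", "shoot", "leaf", "tillering_bud", "stigma", "ovary", "pollen",
    "husk", "pericarp", "SAM", "IM", "embryo", "endosperm",
)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class PlantedGroup:
    """A batch of planted tissue-specific genes targeting one rule.

    ``xmax_range``/``leak_range`` are uniform laws for the target-tissue
    mean and the (constant across replicates) off-target trace expression.
    Defaults guarantee the stated rule analytically: rule 2 plants draw
    xmax from (30, 100) with leak below 0.3 (ratio >= 100, tau > 0.9);
    rule 3 plants have zero leak.
    """

    tissue: str = "root"
    n_genes: int = 50
    criterion: int = 2
    xmax_range: tuple[float, float] | None = None
    leak_range: tuple[float, float] | None = None

    def resolved(self) -> tuple[tuple[float, float], tuple[float, float]]:
        if self.criterion == 2:
            xmax = self.xmax_range or (30.0, 100.0)
            leak = self.leak_range if self.leak_range is not None else (0.0, 0.3)
        elif self.criterion == 3:
            xmax = self.xmax_range or (1.0, 50.0)
            leak = self.leak_range if self.leak_range is not None else (0.0, 0.0)
        elif self.criterion == 1:
            xmax = self.xmax_range or (4.0, 20.0)
            leak = self.leak_range if self.leak_range is not None else (0.0, 0.3)
        else:
            raise ValueError("criterion must be 1, 2 or 3")
        ratio_needed = {1: 4.0, 2: 10.0, 3: None}[self.criterion]
        if self.criterion == 3 and leak != (0.0, 0.0):
            raise ValueError("criterion-3 plants require zero leak")
        if ratio_needed is not None and leak[0] > 0 and xmax[1] / leak[0] < ratio_needed:
            raise ValueError(
                f"infeasible law: leak >= {leak[0]} can never satisfy "
                f"xmax/xsec >= {ratio_needed} with xmax <= {xmax[1]}"
            )
        return xmax, leak


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Study conditions for the synthetic TPM matrix."""

    n_genes: int = 2000
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    replicates: int = 2
    background_log_mean: float = float(np.log(5.0))  # natural-log mean of baseline TPM
    background_log_sd: float = 1.0
    tissue_wobble_sd: float = 0.4   # ln-scale per-tissue deviation of background genes
    replicate_noise_sd: float = 0.2  # ln-scale multiplicative replicate noise
    planted: tuple[PlantedGroup, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.tissues) < 2:
            raise ValueError("need >= 2 tissues")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate per tissue")
        n_planted = sum(g.n_genes for g in self.planted)
        if n_planted > self.n_genes:
            raise ValueError("planted gene count exceeds n_genes")
        for g in self.planted:
            if g.tissue not in self.tissues:
                raise ValueError(f"planted tissue {g.tissue!r} not in tissue list")
            g.resolved()  # feasibility check
        if self.background_log_sd < 0 or self.tissue_wobble_sd < 0 or self.replicate_noise_sd < 0:
            raise ValueError("noise scales must be >= 0")


def simulate_expression(spec: ExpressionSimSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Synthetic TPM matrix plus a truth table of planted specific genes.

    The truth table has columns ``gene_id``, ``tissue``, ``criterion``;
    background genes are absent from it.
    """
    rng = _rng(spec.seed)
    tissues = list(spec.tissues)
    n_bg = spec.n_genes - sum(g.n_genes for g in spec.planted)
    gene_ids = [f"gene_{i:05d}" for i in range(spec.n_genes)]
    order = rng.permutation(spec.n_genes)

    # tissue-level means, genes x tissues
    means = np.empty((spec.n_genes, len(tissues)))
    truth_rows = []
    row = 0
    for grp in spec.planted:
        xmax_rng, leak_rng = grp.resolved()
        t_idx = tissues.index(grp.tissue)
        for _ in range(grp.n_genes):
            leak = rng.uniform(*leak_rng, size=len(tissues)) if leak_rng[1] > 0 else np.zeros(len(tissues))
            leak_row = leak
            xmax = rng.uniform(*xmax_rng)
            means[row] = leak_row
            means[row, t_idx] = xmax
            truth_rows.append((gene_ids[order[row]], grp.tissue, grp.criterion))
            row += 1
    planted_rows = row
    base = np.exp(rng.normal(spec.background_log_mean, spec.background_log_sd, size=n_bg))
    wobble = np.exp(rng.normal(0.0, spec.tissue_wobble_sd, size=(n_bg, len(tissues))))
    means[row:] = base[:, None] * wobble

    # replicate expansion; planted off-target traces stay constant across
    # replicates (residual background, not biological signal)
    sample_ids = [f"{t}_rep{j+1}" for t in tissues for j in range(spec.replicates)]
    tissue_of_sample = {s: s.rsplit("_rep", 1)[0] for s in sample_ids}
    values = np.empty((spec.n_genes, len(sample_ids)))
    for ti, t in enumerate(tissues):
        for j in range(spec.replicates):
            col = ti * spec.replicates + j
            noise = np.exp(rng.normal(0.0, spec.replicate_noise_sd, size=spec.n_genes))
            vals = means[:, ti] * noise
            # keep exact zeros exact and planted leaks un-noised
            vals[:planted_rows] = means[:planted_rows, ti]
            if spec.replicate_noise_sd > 0:
                target_mask = np.zeros(spec.n_genes, bool)
                r0 = 0
                for grp in spec.planted:
                    t_idx = tissues.index(grp.tissue)
                    if t_idx == ti:
                        target_mask[r0 : r0 + grp.n_genes] = True
                    r0 += grp.n_genes
                vals[target_mask] = means[target_mask, ti] * noise[target_mask]
            values[:, col] = vals

    # shuffle rows so planted genes are not positionally clustered
    shuffled = np.empty_like(values)
    shuffled[order] = values
    df = pd.DataFrame(shuffled, index=gene_ids, columns=sample_ids)
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "tissue", "criterion"])
    return ExpressionMatrix(df, tissue_of_sample), truth


# ---------------------------------------------------------------------------
# promoters


@dataclass(frozen=True)
class PlantedMotif:
    """A core to insert with set-specific probabilities."""

    core: str
    fg_probability: float = 0.6
    bg_probability: float = 0.05
    position_law: str = "uniform"  # "uniform" | "3prime"

    def __post_init__(self) -> None:
        validate_motif(self.core)
        for p in (self.fg_probability, self.bg_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.position_law not in ("uniform", "3prime"):
            raise ValueError("position_law must be 'uniform' or '3prime'")


@dataclass(frozen=True)
class PromoterSimSpec:
    n_fg: int = 200
    n_bg: int = 200
    length: int = 1000
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    markov1: tuple | None = None  # optional 4x4 row-stochastic transition table
    planted: tuple[PlantedMotif, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_probs) - 1.0) > 1e-9 or min(self.base_probs) < 0:
            raise ValueError("base_probs must be a probability vector")
        longest = max((len(m.core) for m in self.planted), default=0)
        if self.length < max(longest, 1):
            raise ValueError("length must cover the longest planted motif")
        total = sum(len(m.core) for m in self.planted)
        if total > self.length:
            raise ValueError("planted motifs exceed sequence capacity")


_BASES = np.array(list("ACGT"))


def _random_sequences(rng, n: int, spec: PromoterSimSpec) -> list[str]:
    if spec.markov1 is None:
        idx = rng.choice(4, size=(n, spec.length), p=list(spec.base_probs))
        return ["".join(_BASES[row]) for row in idx]
    P = np.asarray(spec.markov1, float)
    if P.shape != (4, 4) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("markov1 must be a 4x4 row-stochastic matrix")
    seqs = []
    for _ in range(n):
        s = np.empty(spec.length, int)
        s[0] = rng.choice(4, p=list(spec.base_probs))
        for i in range(1, spec.length):
            s[i] = rng.choice(4, p=P[s[i - 1]])
        seqs.append("".join(_BASES[s]))
    return seqs


def _insert(rng, seq: str, motif: str, law: str, occupied: list[tuple[int, int]]):
    m = len(motif)
    L = len(seq)
    for _ in range(200):
        if law == "uniform":
            pos = int(rng.integers(0, L - m + 1))
        else:  # 3'-biased
            pos = int(rng.beta(3.0, 1.0) * (L - m))
        if all(pos + m <= a or pos >= b for a, b in occupied):
            strand = "+" if rng.random() < 0.5 else "-"
            ins = motif if strand == "+" else revcomp(motif)
            occupied.append((pos, pos + m))
            return seq[:pos] + ins + seq[pos + m :], pos, strand
    raise RuntimeError("could not place motif without overlapping prior insertions")


def simulate_promoters(
    spec: PromoterSimSpec,
) -> tuple[PromoterSet, PromoterSet, pd.DataFrame]:
    """Foreground/background promoter sets plus an insertion truth table.

    Motifs are inserted by overwriting (sequence length is preserved) at a
    drawn position and strand; insertions never overlap one another.  The
    truth table has columns ``set``, ``gene_id``, ``motif``, ``position``,
    ``strand``.
    """
    rng = _rng(spec.seed)
    truth_rows = []
    sets = {}
    for label, n, attr in (("fg", spec.n_fg, "fg_probability"),
                           ("bg", spec.n_bg, "bg_probability")):
        seqs = _random_sequences(rng, n, spec)
        records = []
        for i, seq in enumerate(seqs):
            gid = f"{label}_gene_{i:04d}"
            occupied: list[tuple[int, int]] = []
            for pm in spec.planted:
                if rng.random() < getattr(pm, attr):
                    seq, pos, strand = _insert(rng, seq, pm.core, pm.position_law, occupied)
                    truth_rows.append((label, gid, pm.core, pos, strand))
            records.append(
                PromoterRecord(
                    gene_id=gid, sequence=seq, chrom=f"sim_{label}", strand="+",
                    start=i * spec.length, end=(i + 1) * spec.length,
                    requested_length=spec.length,
                )
            )
        sets[label] = PromoterSet(records)
    truth = pd.DataFrame(truth_rows, columns=["set", "gene_id", "motif", "position", "strand"])
    return sets["fg"], sets["bg"], truth


# ---------------------------------------------------------------------------
# orthogroups


@dataclass(frozen=True)
class OrthologySimSpec:
    n_orthogroups: int = 100
    species: tuple[str, ...] = ("arabidopsis", "rice", "maize")
    conserved_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.conserved_fraction <= 1.0:
            raise ValueError("conserved_fraction must lie in [0, 1]")
        if len(self.species) < 2:
            raise ValueError("need >= 2 species")


def simulate_orthogroups(
    spec: OrthologySimSpec, specific_sets: Mapping[str, Sequence[str]]
) -> tuple[OrthogroupTable, pd.DataFrame]:
    """Orthogroup table in which ``conserved_fraction`` of orthogroups hold
    a tissue-specific gene in every species.

    Remaining orthogroups receive filler (non-specific) genes; leftover
    specific genes are spread one-species-per-orthogroup so a non-conserved
    orthogroup can never satisfy the conservation predicate.  The truth
    table lists (orthogroup, species, gene) for conserved placements.
    """
    rng = _rng(spec.seed)
    pools = {sp: list(specific_sets[sp]) for sp in spec.species}
    for sp in spec.species:
        if sp not in specific_sets:
            raise ValueError(f"no specific set for species {sp!r}")
        rng.shuffle(pools[sp])
    n_cons = int(round(spec.conserved_fraction * spec.n_orthogroups))
    for sp, pool in pools.items():
        if len(pool) < n_cons:
            raise ValueError(
                f"species {sp!r} has only {len(pool)} specific genes; "
                f"{n_cons} conserved orthogroups requested"
            )

    members: dict[str, dict[str, list[str]]] = {}
    truth_rows = []
    filler_counter = 0
    for i in range(spec.n_orthogroups):
        og = f"OG{i:07d}"
        per_sp: dict[str, list[str]] = {}
        if i < n_cons:
            for sp in spec.species:
                g = pools[sp].pop()
                per_sp[sp] = [g]
                truth_rows.append((og, sp, g))
        else:
            # at most one species contributes a leftover specific gene
            lucky = spec.species[i % len(spec.species)]
            for sp in spec.species:
                if sp == lucky and pools[sp]:
                    per_sp[sp] = [pools[sp].pop()]
                else:
                    per_sp[sp] = [f"{sp}_filler_{filler_counter:05d}"]
                    filler_counter += 1
        members[og] = per_sp
    table = OrthogroupTable(species=list(spec.species), members=members)
    truth = pd.DataFrame(truth_rows, columns=["orthogroup", "species", "gene_id"])
    return table, truth
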