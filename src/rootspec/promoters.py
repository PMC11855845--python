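"""Promoter extraction: fixed-length sequence upstream of the translation start.

The promoter is defined operationally as the ``length`` bp of genomic
sequence immediately 5' of the ATG (the start of the first CDS of the
representative transcript), strand-corrected so the returned string reads
5'->3' and its final base abuts the A of ATG.  When no annotated CDS
exists the transcript 5' end is used with a warning.  Promoters are
truncated (never padded) at contig boundaries; Ns are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from pyfaidx import Fasta

from ._sequence import revcomp

__all__ = [
    "PromoterRecord",
    "PromoterSet",
    "extract_promoters",
    "read_promoter_fasta",
    "write_promoter_fasta",
    "write_promoter_bed",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PromoterRecord:
    """One upstream sequence with its genomic provenance.

    ``start``/``end`` are 0-based half-open genomic coordinates of the
    extracted interval on the reference (+) strand.
    """

    gene_id: str
    sequence: str
    chrom: str
    strand: str
    start: int
    end: int
    requested_length: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(f"{self.gene_id}: sequence/interval length mismatch")
        if len(self.sequence) > self.requested_length:
            raise ValueError(f"{self.gene_id}: sequence longer than requested")

    @property
    def actual_length(self) -> int:
        return len(self.sequence)


class PromoterSet:
    """Ordered collection of promoter records, addressable by gene id."""

    def __init__(self, records: Sequence[PromoterRecord]):
        self.records = list(records)
        self._by_gene = {r.gene_id: r for r in self.records}
        if len(self._by_gene) != len(self.records):
            raise ValueError("duplicate gene ids in promoter set")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_gene

    def __getitem__(self, gene_id: str) -> PromoterRecord:
        return self._by_gene[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def subset(self, gene_ids: Iterable[str]) -> "PromoterSet":
        wanted = set(gene_ids)
        return PromoterSet([r for r in self.records if r.gene_id in wanted])


def _representative_cds_start(db: gffutils.FeatureDB, gene) -> tuple[int, int, str] | None:
    """Translation-start info for the transcript with the longest CDS sum.

    Returns (tls_genomic_0based, strand_sign, transcript_id) where the TLS
    is the first CDS base in transcript orientation, or None when the gene
    has no CDS.
    """
    best = None  # (cds_total, transcript_id, cds_list)
    for tx in db.children(gene, level=1):
        cds = list(db.children(tx, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        total = sum(c.end - c.start + 1 for c in cds)
        key = (total, tx.id)
        if best is None or key > (best[0], best[1]):
            best = (total, tx.id, cds)
    if best is None:
        # CDS attached directly to the gene (minimal annotations)
        cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not cds:
            return None
        best = (sum(c.end - c.start + 1 for c in cds), gene.id, cds)
    _, tx_id, cds = best
    if gene.strand == "-":
        tls = max(c.end for c in cds)  # 1-based inclusive end == 0-based exclusive
        return tls, -1, tx_id
    tls = min(c.start for c in cds) - 1  # to 0-based
    return tls, +1, tx_id


def _transcript_five_prime(db: gffutils.FeatureDB, gene) -> tuple[int, int]:
    if gene.strand == "-":
        return gene.end, -1
    return gene.start - 1, +1


def extract_promoters(
    genome: str | Path | Fasta,
    annotation: str | Path | gffutils.FeatureDB,
    gene_ids: Sequence[str],
    length: int,
) -> PromoterSet:
    """Extract ``length`` bp upstream of the ATG for each requested gene.

    ``genome`` is a FASTA path (indexed on first use) or an open
    :class:`pyfaidx.Fasta`; ``annotation`` a GFF3 path or a prebuilt
    :class:`gffutils.FeatureDB`.  Unknown gene ids raise a single error
    listing all of them.
    """
    if length <= 0:
        raise ValueError("promoter length must be > 0")
    fa = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    if isinstance(annotation, gffutils.FeatureDB):
        db = annotation
    else:
        db = gffutils.create_db(
            str(annotation), ":memory:", merge_strategy="create_unique", keep_order=True
        )

    missing = []
    found = {}
    for gid in gene_ids:
        try:
            found[gid] = db[gid]
        except gffutils.FeatureNotFoundError:
            missing.append(gid)
    if missing:
        raise KeyError(f"gene ids not found in annotation: {missing}")

    records = []
    for gid in gene_ids:
        gene = found[gid]
        info = _representative_cds_start(db, gene)
        if info is None:
            logger.warning("%s: no CDS; falling back to transcript 5' end", gid)
            tls, sign = _transcript_five_prime(db, gene)
        else:
            tls, sign, tx_id = info
            logger.debug("%s: representative transcript %s", gid, tx_id)
        contig = fa[gene.seqid]
        contig_len = len(contig)
        if sign > 0:
            start, end = max(0, tls - length), tls
            seq = contig[start:end].seq.upper()
        else:
            start, end = tls, min(contig_len, tls + length)
            seq = revcomp(contig[start:end].seq.upper())
        if end - start < length:
            logger.info(
                "%s: promoter truncated at contig boundary (%d < %d bp)",
                gid, end - start, length,
            )
        records.append(
            PromoterRecord(
                gene_id=gid,
                sequence=seq,
                chrom=gene.seqid,
                strand="+" if sign > 0 else "-",
                start=start,
                end=end,
                requested_length=length,
            )
        )
    return PromoterSet(records)


def write_promoter_fasta(pset: PromoterSet, path: str | Path) -> None:
    """FASTA with ``gene_id::chrom:start-end(strand)`` headers."""
    with open(path, "w") as fh:
        for r in pset:
            fh.write(f">{r.gene_id}::{r.chrom}:{r.start}-{r.end}({r.strand})\n")
            for i in range(0, len(r.sequence), 70):
                fh.write(r.sequence[i : i + 70] + "\n")


def read_promoter_fasta(path: str | Path) -> PromoterSet:
    """Read a promoter FASTA; provenance fields are recovered from the
    header when it follows the writer's convention, else synthesized."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        name = rec.id
        chrom, strand, start, end = name, "+", 0, len(seq)
        if "::" in name:
            name, loc = name.split("::", 1)
            try:
                chrom, rest = loc.split(":", 1)
                coords, strand = rest[:-1].split("("), rest[-2]
                start, end = (int(v) for v in coords[0].split("-"))
            except (ValueError, IndexError):
                chrom, strand, start, end = name, "+", 0, len(seq)
        records.append(
            PromoterRecord(
                gene_id=name,
                sequence=seq,
                chrom=chrom,
                strand=strand if strand in "+-" else "+",
                start=start,
                end=end,
                requested_length=max(len(seq), end - start),
            )
        )
    return PromoterSet(records)


def write_promoter_bed(pset: PromoterSet, path: str | Path) -> None:
    """BED6 of the extracted intervals."""
    with open(path, "w") as fh:
        for r in pset:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n"
            )
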