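"""Small DNA-string utilities shared across the motif modules.

All motif-level operations in this package work on plain uppercase strings.
Reverse-complement canonicalization maps a k-mer and its reverse complement
to a single representative (the lexicographically smaller of the two), so
that both-strand counting never double-books a site.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")

#: IUPAC ambiguity code for each non-empty subset of {A, C, G, T}.
IUPAC_FOR_BASES = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

UNAMBIGUOUS = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement.

    Palindromic k-mers (equal to their reverse complement) map to
    themselves, making the operation idempotent.
    """
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def is_palindromic(kmer: str) -> bool:
    return kmer == revcomp(kmer)


def validate_motif(motif: str) -> str:
    """Uppercase and check that a motif core contains only A/C/G/T."""
    m = motif.upper()
    bad = set(m) - UNAMBIGUOUS
    if bad:
        raise ValueError(
            f"motif {motif!r} contains non-ACGT symbols: {sorted(bad)}"
        )
    if not m:
        raise ValueError("empty motif")
    return m


def unambiguous_runs(seq: str) -> list[str]:
    """Split a (possibly IUPAC-degenerate) string into maximal A/C/G/T runs.

    Ambiguous positions break continuity and are dropped.
    """
    runs: list[str] = []
    cur: list[str] = []
    for ch in seq.upper():
        if ch in UNAMBIGUOUS:
            cur.append(ch)
        else:
            if cur:
                runs.append("".join(cur))
            cur = []
    if cur:
        runs.append("".join(cur))
    return runs
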