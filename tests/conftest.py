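import textwrap

import pandas as pd
import pytest

from rootspec.expression import ExpressionMatrix


@pytest.fixture
def small_matrix():
    """3 genes x 4 samples, 2 tissues (2 replicates each)."""
    df = pd.DataFrame(
        {
            "root_r1": [10.0, 0.0, 5.0],
            "root_r2": [20.0, 0.0, 5.0],
            "leaf_r1": [0.0, 8.0, 5.0],
            "leaf_r2": [0.0, 12.0, 5.0],
        },
        index=["gA", "gB", "gC"],
    )
    tissues = {"root_r1": "root", "root_r2": "root",
               "leaf_r1": "leaf", "leaf_r2": "leaf"}
    return ExpressionMatrix(df, tissues)


@pytest.fixture
def tiny_genome(tmp_path):
    """Small two-contig genome + GFF3 with +/- strand genes.

    chr1 (+ strand gene gplus): CDS starts at 1-based 121 -> TLS 0-based 120.
    chr2 (- strand gene gminus): CDS ends at 1-based 180 -> TLS 0-based 180.
    """
    import numpy as np

    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    chr1 = "".join(bases[rng.integers(0, 4, 300)])
    chr2 = "".join(bases[rng.integers(0, 4, 300)])
    fasta = tmp_path / "genome.fa"
    fasta.write_text(f">chr1\n{chr1}\n>chr2\n{chr2}\n")

    gff = tmp_path / "genes.gff3"
    gff.write_text(textwrap.dedent("""\
        ##gff-version 3
        chr1\tsrc\tgene\t121\t240\t.\t+\t.\tID=gplus
        chr1\tsrc\tmRNA\t121\t240\t.\t+\t.\tID=gplus.t1;Parent=gplus
        chr1\tsrc\tCDS\t121\t240\t.\t+\t0\tID=gplus.t1.cds;Parent=gplus.t1
        chr2\tsrc\tgene\t61\t180\t.\t-\t.\tID=gminus
        chr2\tsrc\tmRNA\t61\t180\t.\t-\t.\tID=gminus.t1;Parent=gminus
        chr2\tsrc\tCDS\t61\t180\t.\t-\t0\tID=gminus.t1.cds;Parent=gminus.t1
    """))
    return {"fasta": fasta, "gff": gff, "chr1": chr1, "chr2": chr2}
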