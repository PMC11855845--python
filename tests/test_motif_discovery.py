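import textwrap

import pytest

from rootspec._sequence import canonical, revcomp
from rootspec.motif_discovery import (
    MotifReport,
    ReportedMotif,
    consensus_cores,
    enrichment_to_report,
    enumerate_enriched_kmers,
    parse_motif_report,
    truncate_reports_to_cores,
    truncate_to_cores,
)
from rootspec.promoters import PromoterRecord, PromoterSet
from rootspec.synthetic import PlantedMotif, PromoterSimSpec, simulate_promoters


def pset_from(seqs, prefix="g"):
    L = max(len(s) for s in seqs)
    return PromoterSet([
        PromoterRecord(f"{prefix}{i}", s, "sim", "+", 0, len(s), L)
        for i, s in enumerate(seqs)
    ])


class TestEnumerate:
    def test_single_promoter_palindromic_candidate_set(self):
        fg = pset_from(["ACGTACGT"])
        bg = pset_from(["TTTTTTTT"])
        res = [e for e in enumerate_enriched_kmers(fg, bg, [8]) if len(e.kmer) == 8]
        assert [e.kmer for e in res] == ["ACGTACGT"]  # collapses with its own revcomp

    def test_identical_fg_and_bg_give_no_signal(self):
        seqs = ["ACGTAGCTTGCAGT" * 20] * 10
        fg, bg = pset_from(seqs, "f"), pset_from(seqs, "b")
        res = enumerate_enriched_kmers(fg, bg, range(6, 8), top=None)
        assert res and all(e.q_value > 0.05 for e in res)

    def test_planted_8mer_ranks_first(self):
        spec = PromoterSimSpec(
            n_fg=200, n_bg=200, length=1000, seed=11,
            planted=(PlantedMotif("AATTAATC", 0.6, 0.05),),
        )
        fg, bg, _truth = simulate_promoters(spec)
        res = [e for e in enumerate_enriched_kmers(fg, bg, [8], top=10)]
        assert res[0].kmer == canonical("AATTAATC")
        assert res[0].q_value < 1e-10

    def test_reverse_strand_occurrences_are_counted(self):
        import numpy as np

        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        motif = "AAATTTGC"

        def flank(n):
            return "".join(bases[rng.integers(0, 4, n)])

        # the motif appears only as its reverse complement on the stored strand
        fg = pset_from([flank(50) + revcomp(motif) + flank(50) for _ in range(5)], "f")
        bg = pset_from([flank(108) for _ in range(5)], "b")
        res = enumerate_enriched_kmers(fg, bg, [8], top=5)
        assert res[0].kmer == canonical(motif)
        assert res[0].fg_genes_with == 5

    def test_short_promoters_contribute_nothing(self):
        fg = pset_from(["ACGTA", "ACGTACGTAC"])  # first is shorter than k
        bg = pset_from(["GGGGGGGGGG"])
        res = enumerate_enriched_kmers(fg, bg, [8], top=None)
        assert all(e.fg_genes_with <= 1 for e in res)

    def test_rejects_bad_k_and_empty_sets(self):
        fg = pset_from(["ACGTACGT"])
        with pytest.raises(ValueError):
            enumerate_enriched_kmers(fg, fg, [3])
        with pytest.raises(ValueError):
            enumerate_enriched_kmers(PromoterSet([]), fg, [6])


class TestParseReports:
    def test_meme_minimal_consensus_rules(self, tmp_path):
        p = tmp_path / "m.meme"
        p.write_text(textwrap.dedent("""\
            MEME version 4

            ALPHABET= ACGT

            MOTIF M1
            letter-probability matrix: alength= 4 w= 4 nsites= 20 E= 1e-5
            0.90 0.05 0.03 0.02
            0.50 0.03 0.02 0.45
            0.10 0.30 0.30 0.30
            0.02 0.03 0.05 0.90
        """))
        rep = parse_motif_report(p, "meme_minimal", tool="homer", background="embryo")
        # col1 max 0.9 -> A; col2 max 0.5 < 0.6, bases >= 0.25 = {A,T} -> W;
        # col3 max 0.3 < 0.6, bases >= 0.25 = {C,G,T} -> B; col4 -> T
        assert [m.consensus for m in rep.motifs] == ["AWBT"]

    def test_meme_minimal_rejects_bad_pwm_rows(self, tmp_path):
        p = tmp_path / "bad.meme"
        p.write_text(
            "MOTIF M1\n"
            "letter-probability matrix: alength= 4 w= 1\n"
            "0.90 0.30 0.03 0.02\n"
        )
        with pytest.raises(ValueError, match="sum to 1"):
            parse_motif_report(p, "meme_minimal", tool="homer")

    def test_consensus_list_ranks_lines(self, tmp_path):
        p = tmp_path / "motifs.txt"
        p.write_text("AATTAATC\n# comment\nACGTGC\nAAAATTTGA\n")
        rep = parse_motif_report(p, "consensus_list", tool="weeder")
        assert [(m.consensus, m.rank) for m in rep.motifs] == [
            ("AATTAATC", 1), ("ACGTGC", 2), ("AAAATTTGA", 3)]

    def test_unknown_dialect(self, tmp_path):
        p = tmp_path / "x"
        p.write_text("ACGTACGT\n")
        with pytest.raises(ValueError, match="dialect"):
            parse_motif_report(p, "jaspar", tool="t")


def report(motifs, tool="t1", background="none"):
    return MotifReport(tool=tool, background=background, motifs=[
        ReportedMotif(consensus=m, score=0.0, rank=i + 1) for i, m in enumerate(motifs)
    ])


class TestTruncateToCores:
    def test_unambiguous_8mer_yields_all_nested_cores(self):
        cores = truncate_to_cores(report(["AATTAATC"]))
        expected = set()
        s = "AATTAATC"
        for k in (6, 7, 8):
            for i in range(len(s) - k + 1):
                expected.add(canonical(s[i:i + k]))
        assert cores == expected
        assert canonical("AATTAATC") in cores

    def test_ambiguity_breaks_continuity(self):
        # W splits ACWTGCA into AC and TGCA; no segment reaches 6 bp
        assert truncate_to_cores(report(["ACWTGCA"])) == set()

    def test_short_motif_yields_nothing(self):
        assert truncate_to_cores(report(["ACGTA"])) == set()

    def test_output_size_bound(self):
        for s in ["ACGTACGTACGT", "AATTAATC", "ACGTAC"]:
            bound = sum(max(0, len(s) - k + 1) for k in range(6, 10))
            assert len(truncate_to_cores(report([s]))) <= bound

    def test_canonicalization_consistent_with_enumerator(self):
        cores = truncate_to_cores(report(["GATTAATT"]))  # revcomp of AATTAATC
        assert canonical("GATTAATT") in cores
        assert all(c == canonical(c) for c in cores)


class TestConsensusCores:
    def test_two_tools_one_background_each_gives_single_star(self):
        per = {
            ("homer", "embryo"): {"AATTAATC"},
            ("bioprospector", "embryo"): {"AATTAATC"},
        }
        cores = consensus_cores(per, min_tools=2)
        assert len(cores) == 1
        c = cores[0]
        assert c.sequence == "AATTAATC" and c.star_class == "*"
        assert c.per_tool_star == {"bioprospector": "*", "homer": "*"}

    def test_both_backgrounds_for_one_tool_gives_double_star(self):
        per = {
            ("homer", "embryo"): {"AATTAATC"},
            ("homer", "endosperm"): {"AATTAATC"},
            ("xstreme", "embryo"): {"AATTAATC"},
        }
        cores = consensus_cores(per, min_tools=2)
        assert cores[0].star_class == "**"
        assert cores[0].per_tool_star["homer"] == "**"
        assert cores[0].per_tool_star["xstreme"] == "*"

    def test_single_tool_support_is_excluded(self):
        per = {
            ("homer", "embryo"): {"AATTAATC", "ACGTGCAT"},
            ("weeder", "none"): {"ACGTGCAT"},
        }
        cores = consensus_cores(per, min_tools=2)
        assert [c.sequence for c in cores] == ["ACGTGCAT"]
        assert cores[0].weeder_flag is True
        assert cores[0].star_class == "*"  # homer found it under one background

    def test_background_runs_of_same_tool_count_once(self):
        per = {
            ("homer", "embryo"): {"AATTAATC"},
            ("homer", "endosperm"): {"AATTAATC"},
        }
        with pytest.raises(ValueError):
            consensus_cores(per, min_tools=2)  # only one distinct tool present

    def test_monotone_in_min_tools(self):
        per = {
            ("homer", "embryo"): {"AAAAAT", "CCCGGGA"},
            ("xstreme", "endosperm"): {"AAAAAT"},
            ("weeder", "none"): {"AAAAAT", "CCCGGGA"},
        }
        got1 = {c.sequence for c in consensus_cores(per, min_tools=1)}
        got2 = {c.sequence for c in consensus_cores(per, min_tools=2)}
        assert got2 <= got1

    def test_end_to_end_planted_recovery_with_double_star(self, tmp_path):
        """Plant a core, discover it against two synthetic backgrounds, add an
        external superstring report, and recover it with star class **."""
        planted = "AATTAATC"
        fg, bg_embryo, _ = simulate_promoters(PromoterSimSpec(
            n_fg=120, n_bg=120, length=600, seed=5,
            planted=(PlantedMotif(planted, 0.6, 0.05),)))
        _, bg_endosperm, _ = simulate_promoters(PromoterSimSpec(
            n_fg=1, n_bg=120, length=600, seed=6,
            planted=(PlantedMotif(planted, 0.0, 0.05),)))
        reports = []
        for bg, label in [(bg_embryo, "embryo"), (bg_endosperm, "endosperm")]:
            enr = enumerate_enriched_kmers(fg, bg, range(6, 10), top=20)
            reports.append(enrichment_to_report(enr, tool="rootspec-enum",
                                                background=label))
        ext = tmp_path / "external.txt"
        ext.write_text("C" + planted + "A\n")  # 10-mer superstring
        reports.append(parse_motif_report(ext, "consensus_list", tool="external"))
        per = truncate_reports_to_cores(reports)
        cores = consensus_cores(per, min_tools=2)
        hit = {c.sequence: c for c in cores}[canonical(planted)]
        assert hit.star_class == "**"
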