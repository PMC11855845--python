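"""End-to-end orchestration: expression -> specificity -> orthology ->
promoters -> motif discovery -> scanning/frequency, with a JSON manifest.

The pipeline is configured by a single declarative TOML file (or a
:class:`PipelineConfig` built in code); all screening constants and motif
parameters are configuration defaults, never hard-coded, so reproduction
attempts can vary them.  Stage outputs are TSV/FASTA files under the
output directory; the manifest records inputs, parameter values, the seed
and per-stage record counts, and is byte-stable for identical inputs.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .expression import aggregate_replicates, read_expression_tsv, write_tissue_matrix
from .motif_discovery import (
    consensus_cores,
    enrichment_to_report,
    enumerate_enriched_kmers,
    parse_motif_report,
    truncate_reports_to_cores,
    write_cores_tsv,
)
from .motif_scan import compare_frequencies, frequency, occurrences_to_frame, scan
from .orthology import conserved_specific, read_orthogroups, write_conserved_tsv
from .promoters import extract_promoters, read_promoter_fasta, write_promoter_fasta
from .specificity import ScreeningThresholds, call_tissue_genes, write_results_tsv

logger = logging.getLogger(__name__)

__all__ = ["SpeciesConfig", "ExternalReport", "PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class SpeciesConfig:
    name: str
    matrix: str
    tissue_map: str
    genome: str | None = None
    gff: str | None = None
    promoters_fasta: str | None = None  # precomputed promoters, alternative to genome+gff
    promoter_length: int = 3000

    def __post_init__(self) -> None:
        if self.promoter_length <= 0:
            raise ValueError("promoter length must be > 0")


@dataclass
class ExternalReport:
    tool: str
    background: str
    dialect: str
    path: str


@dataclass
class PipelineConfig:
    species: list[SpeciesConfig]
    out_dir: str
    focal_species: str | None = None
    focal_tissue: str = "root"
    background_tissues: tuple[str, ...] = ("embryo", "endosperm")
    orthogroups: str | None = None
    thresholds: ScreeningThresholds = field(default_factory=ScreeningThresholds)
    k_min: int = 6
    k_max: int = 9
    top_kmers: int = 100
    min_tools: int = 2
    external_reports: list[ExternalReport] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("at least one species required")
        if not 0.0 < self.thresholds.tau_min < 1.0:
            raise ValueError("tau_min must lie in (0, 1)")
        if not (4 <= self.k_min <= self.k_max <= 12):
            raise ValueError("k range must lie within 4..12")
        if self.focal_species is None:
            self.focal_species = self.species[0].name
        if self.focal_species not in {s.name for s in self.species}:
            raise ValueError(f"unknown focal species {self.focal_species!r}")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a TOML file."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    species = [SpeciesConfig(**s) for s in raw.pop("species", [])]
    reports = [ExternalReport(**r) for r in raw.pop("external_reports", [])]
    th = ScreeningThresholds(**raw.pop("thresholds", {}))
    bg = tuple(raw.pop("background_tissues", ("embryo", "endosperm")))
    return PipelineConfig(
        species=species, external_reports=reports, thresholds=th,
        background_tissues=bg, **raw,
    )


def _promoters_for(sp: SpeciesConfig, gene_ids, out_path: Path):
    if sp.promoters_fasta:
        pset = read_promoter_fasta(sp.promoters_fasta).subset(gene_ids)
    elif sp.genome and sp.gff:
        pset = extract_promoters(sp.genome, sp.gff, list(gene_ids), sp.promoter_length)
    else:
        return None
    write_promoter_fasta(pset, out_path)
    return pset


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Execute all configured stages; returns (and writes) the manifest."""
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "focal_tissue": config.focal_tissue,
            "background_tissues": list(config.background_tissues),
            "tau_min": config.thresholds.tau_min,
            "k_range": [config.k_min, config.k_max],
            "min_tools": config.min_tools,
            "top_kmers": config.top_kmers,
        },
        "inputs": {s.name: s.matrix for s in config.species},
        "stages": [],
    }

    def stage(name: str, **counts):
        manifest["stages"].append({"name": name, "counts": counts})
        logger.info("stage %s: %s", name, counts)

    # expression + specificity, per species
    tissue_calls: dict[str, dict[str, set[str]]] = {}
    profiles_by_species = {}
    for sp in config.species:
        m = read_expression_tsv(sp.matrix, sp.tissue_map)
        profiles = aggregate_replicates(m)
        profiles_by_species[sp.name] = profiles
        write_tissue_matrix(profiles, out / f"{sp.name}.tissue_tpm.tsv")
        stage(f"expression[{sp.name}]", genes=len(profiles), tissues=profiles[0].n_tissues,
              samples=len(m.sample_ids))
        calls = {}
        tissues_present = set(profiles[0].tissues)
        for tissue in {config.focal_tissue, *config.background_tissues} & tissues_present:
            res = call_tissue_genes(profiles, tissue, config.thresholds)
            write_results_tsv(res, out / f"{sp.name}.{tissue}.specific.tsv")
            calls[tissue] = {r.gene_id for r in res}
        tissue_calls[sp.name] = calls
        stage(f"specificity[{sp.name}]",
              **{t: len(g) for t, g in sorted(calls.items())})

    # orthology (optional)
    if config.orthogroups and len(config.species) >= 2:
        og = read_orthogroups(config.orthogroups)
        focal = config.focal_species
        required = [s.name for s in config.species if s.name != focal]
        cs = conserved_specific(
            {name: calls.get(config.focal_tissue, set())
             for name, calls in tissue_calls.items()},
            og, focal, required,
        )
        write_conserved_tsv(cs, out / f"{focal}.conserved.tsv")
        stage("orthology", conserved=len(cs.genes), orthogroups=len(og.members))

    # promoters for the focal species (focal + background tissue gene sets)
    focal_sp = next(s for s in config.species if s.name == config.focal_species)
    focal_calls = tissue_calls[focal_sp.name]
    fg_genes = sorted(focal_calls.get(config.focal_tissue, set()))
    psets = {}
    fg_pset = _promoters_for(focal_sp, fg_genes,
                             out / f"{focal_sp.name}.{config.focal_tissue}.promoters.fa")
    if fg_pset is None:
        stage("promoters", skipped=1)
        manifest["stages"][-1]["note"] = "no genome/annotation or promoter FASTA configured"
        _write_manifest(manifest, out)
        return manifest
    psets[config.focal_tissue] = fg_pset
    for bg_tissue in config.background_tissues:
        genes = sorted(focal_calls.get(bg_tissue, set()))
        p = _promoters_for(focal_sp, genes,
                           out / f"{focal_sp.name}.{bg_tissue}.promoters.fa")
        if p is not None and len(p):
            psets[bg_tissue] = p
    stage("promoters", **{t: len(p) for t, p in sorted(psets.items())})

    # motif discovery: built-in enumerator vs each background + external reports
    k_range = range(config.k_min, config.k_max + 1)
    reports = []
    for bg_tissue in config.background_tissues:
        if bg_tissue not in psets or len(psets[bg_tissue]) == 0:
            continue
        enr = enumerate_enriched_kmers(fg_pset, psets[bg_tissue], k_range, config.top_kmers)
        reports.append(enrichment_to_report(enr, tool="rootspec-enum", background=bg_tissue))
    for er in config.external_reports:
        reports.append(parse_motif_report(er.path, er.dialect, er.tool, er.background))
    per_report = truncate_reports_to_cores(reports, k_range)
    n_tools = len({tool for tool, _ in per_report})
    if n_tools >= 2:
        cores = consensus_cores(per_report, config.min_tools, species=focal_sp.name)
        core_strings = [c.sequence for c in cores]
        write_cores_tsv(cores, out / "motif_cores.tsv")
        stage("motif_discovery", reports=len(reports), cores=len(cores))
    else:
        # single tool: keep its cores without cross-tool consensus
        core_strings = sorted(set().union(*per_report.values())) if per_report else []
        (out / "motif_cores.tsv").write_text(
            "sequence\n" + "".join(f"{c}\n" for c in core_strings)
        )
        stage("motif_discovery", reports=len(reports), cores=len(core_strings))

    # scanning + frequency across tissue gene sets
    if core_strings:
        all_occ = []
        gene_sets = {}
        for tissue, pset in psets.items():
            all_occ.extend(scan(pset, core_strings, strands="both"))
            gene_sets[tissue] = set(pset.gene_ids)
        freq = frequency(all_occ, gene_sets)
        freq.write_tsv(out / "motif_frequency.tsv")
        occurrences_to_frame(all_occ).to_csv(out / "motif_occurrences.tsv",
                                             sep="\t", index=False)
        bg_all = set().union(*(gene_sets[t] for t in gene_sets if t != config.focal_tissue)) \
            if len(gene_sets) > 1 else set()
        if bg_all:
            cmp_df = compare_frequencies(all_occ, gene_sets[config.focal_tissue], bg_all)
            cmp_df.to_csv(out / "motif_frequency_tests.tsv", sep="\t", index=False)
        stage("motif_scan", motifs=len(core_strings),
              sites=int(sum(o.count for o in all_occ)))
    else:
        stage("motif_scan", motifs=0, sites=0)

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
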