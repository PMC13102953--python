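"""End-to-end orchestration: simulate/load → filter → coverage → SNP scan
→ k-mer scan → region validation → heterogamety call.

`analyse` runs the whole chain in memory; `run_all` wraps it with file
input/output and writes a manifest (parameter echo, per-file SHA-256) so
that reruns with the same configuration are verifiably bit-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .caller import UNDETERMINED, SexSystemCall, call_system
from .cohort import SexedCohort, read_sample_sheet
from .coverage import CoverageScanResult, coverage_scan
from .fileio import (
    read_depth_table,
    read_fasta,
    write_fasta,
    write_json,
    write_windows,
)
from .kmer import (
    assemble_contigs,
    build_matrix,
    count_kmers,
    filter_maf_mac,
    kmer_association,
    place_contigs,
    top_kmers,
)
from .simulate import SimulatedData, SimulationConfig, simulate_cohort, write_simulation
from .snp import (
    ScanParameters,
    SnpScanResult,
    randomisation_control,
    scaled_top_k,
    snp_scan,
)
from .validate import (
    GenotypePatternSummary,
    classical_mds,
    genotype_distance,
    genotype_pattern,
    heatmap_matrix,
)
from .variants import (
    FilterReport,
    GenotypeTable,
    VariantFilterSpec,
    filter_variants,
    read_vcf,
    write_vcf,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # input: either a simulation or file paths
    simulation: Optional[SimulationConfig] = None
    sample_sheet: Optional[str] = None
    vcf: Optional[str] = None
    sequences_dir: Optional[str] = None
    depth: Optional[str] = None
    reference: Optional[str] = None
    # stage parameters
    filter: VariantFilterSpec = field(default_factory=VariantFilterSpec)
    scan: ScanParameters = field(default_factory=ScanParameters)
    auto_top_k: bool = False  # scale the integration depth to the window count
    coverage_eps: float = 0.5
    coverage_threshold: float = 1.0
    coverage_min_run: int = 5
    k: int = 31
    min_support: int = 5
    min_canonical_frac: float = 0.20
    maf_min: float = 0.05
    mac_min: int = 5
    significance_quantile: Optional[float] = None  # None = ties at minimum p
    randomisation_rounds: int = 0
    min_share: float = 2 / 3

    def validate(self) -> None:
        if self.simulation is None:
            if not (self.sample_sheet and self.vcf):
                raise ValueError(
                    "config needs either a simulation block or sample_sheet+vcf paths"
                )


@dataclass
class AnalysisResult:
    call: SexSystemCall
    filter_report: FilterReport
    filtered: GenotypeTable
    scan: SnpScanResult
    params: ScanParameters
    coverage: Optional[CoverageScanResult] = None
    kmer_association: Optional[pd.DataFrame] = None
    kmer_significant: Optional[pd.DataFrame] = None
    contigs: list[str] = field(default_factory=list)
    placements: Optional[pd.DataFrame] = None
    contigs_per_mb: Optional[pd.DataFrame] = None
    regions: list[dict] = field(default_factory=list)
    pattern: Optional[GenotypePatternSummary] = None
    validation: list[dict] = field(default_factory=list)
    randomisation: Optional[dict] = None

    @property
    def candidates(self) -> list[dict]:
        return self.scan.candidates


def analyse(
    cohort: SexedCohort,
    genotypes: GenotypeTable,
    config: PipelineConfig,
    depth: Optional[pd.DataFrame] = None,
    reference: Optional[Mapping[str, str]] = None,
    sequences: Optional[Mapping[str, list[str]]] = None,
) -> AnalysisResult:
    """Run filter → coverage → SNP scan → k-mer scan → validation → call."""
    filtered, report = filter_variants(genotypes, config.filter)
    log.info("filter: %d -> %d sites", report.n_input, report.n_retained)

    coverage_result = None
    if depth is not None:
        coverage_result = coverage_scan(
            depth,
            eps=config.coverage_eps,
            threshold=config.coverage_threshold,
            min_run=config.coverage_min_run,
        )

    params = config.scan
    if config.auto_top_k:
        n_windows = len(
            set(
                zip(
                    filtered.chrom.tolist(),
                    ((filtered.pos - 1) // params.window).tolist(),
                )
            )
        )
        params = ScanParameters(
            window=params.window,
            top_fraction=params.top_fraction,
            n_perm=params.n_perm,
            alpha=params.alpha,
            top_k=scaled_top_k(max(n_windows, 1)),
            seed=params.seed,
        )
    scan = snp_scan(filtered, cohort, params)
    log.info("snp-scan: %d candidate region(s)", len(scan.candidates))

    randomisation = None
    if config.randomisation_rounds > 0:
        randomisation = randomisation_control(
            filtered,
            cohort,
            params,
            n_rounds=config.randomisation_rounds,
            seed=params.seed + 1,
            original=scan,
        )

    assoc = significant = placements = per_mb = None
    contigs: list[str] = []
    kmer_regions: list[dict] = []
    if sequences is not None:
        counts = {sid: count_kmers(frags, config.k) for sid, frags in sequences.items()}
        matrix = build_matrix(
            counts,
            cohort,
            min_support=config.min_support,
            min_canonical_frac=config.min_canonical_frac,
        )
        matrix = filter_maf_mac(matrix, maf_min=config.maf_min, mac_min=config.mac_min)
        log.info("kmer-scan: %d k-mers pass filters", matrix.n_kmers)
        if matrix.n_kmers > 0:
            assoc = kmer_association(matrix, cohort)
            significant = top_kmers(assoc, quantile=config.significance_quantile)
            contigs = assemble_contigs(significant["kmer"].tolist(), k=config.k)
            if reference is not None and contigs:
                placements, per_mb = place_contigs(contigs, reference)
                w = params.window
                exact = placements[placements["match"] == "exact"]
                for _, row in exact.iterrows():
                    kmer_regions.append(
                        {
                            "chrom": row["chrom"],
                            "start": int(row["start"] // w) * w,
                            "end": (int(row["end"] - 1) // w + 1) * w,
                            "source": "kmer",
                        }
                    )

    regions = [dict(r, source="snp") for r in scan.candidates]
    seen = {(r["chrom"], r["start"], r["end"]) for r in regions}
    for r in kmer_regions:
        key = (r["chrom"], r["start"], r["end"])
        if key not in seen:
            regions.append(r)
            seen.add(key)

    pattern = None
    validation: list[dict] = []
    region_tables: list[GenotypeTable] = []
    if regions:
        region_tables = [
            filtered.region(r["chrom"], r["start"], r["end"]) for r in regions
        ]
        merged = _concat_tables(region_tables, filtered)
        pattern = genotype_pattern(merged, cohort)
        for r, tab in zip(regions, region_tables):
            entry = {**r, "n_snps": tab.n_sites}
            if tab.n_sites >= 1:
                dist = genotype_distance(tab, cohort)
                if not np.isnan(dist).any():
                    mds = classical_mds(dist, dims=2, samples=cohort.ids)
                    entry["mds_concordance"] = {
                        sex: list(v) for sex, v in mds.concordance(cohort).items()
                    }
            validation.append(entry)

    snp_empty = pattern is None or pattern.empty
    kmer_empty = significant is None or significant.empty
    if snp_empty and kmer_empty:
        call = SexSystemCall(
            verdict=UNDETERMINED, snp_vote=None, kmer_vote=None, min_share=config.min_share
        )
    else:
        call = call_system(pattern, significant, min_share=config.min_share)

    return AnalysisResult(
        call=call,
        filter_report=report,
        filtered=filtered,
        scan=scan,
        params=params,
        coverage=coverage_result,
        kmer_association=assoc,
        kmer_significant=significant,
        contigs=contigs,
        placements=placements,
        contigs_per_mb=per_mb,
        regions=regions,
        pattern=pattern,
        validation=validation,
        randomisation=randomisation,
    )


@dataclass
class PipelineResult:
    call: SexSystemCall
    candidates: list[dict]
    outdir: Path
    manifest: dict
    analysis: Optional[AnalysisResult] = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        sim: Optional[SimulatedData] = None
        if config.simulation is not None:
            sim = simulate_cohort(config.simulation)
            write_simulation(sim, outdir / "sim")
            cohort, genotypes = sim.cohort, sim.genotypes
            depth, reference, sequences = sim.depth, sim.reference, sim.sequences
        else:
            cohort = read_sample_sheet(config.sample_sheet)
            genotypes = read_vcf(config.vcf, cohort)
            depth = read_depth_table(config.depth) if config.depth else None
            reference = read_fasta(config.reference) if config.reference else None
            sequences = None
            if config.sequences_dir:
                seq_dir = Path(config.sequences_dir)
                sequences = {
                    s.id: list(read_fasta(seq_dir / f"{s.id}.fa").values())
                    for s in cohort
                }

        stage = "analyse"
        res = analyse(
            cohort,
            genotypes,
            config,
            depth=depth,
            reference=reference,
            sequences=sequences,
        )

        stage = "write-outputs"
        write_vcf(res.filtered, outdir / "filtered.vcf")
        write_json(vars(res.filter_report), outdir / "filter_report.json")
        if res.coverage is not None:
            write_windows(res.coverage.windows, outdir / "coverage_windows.tsv")
            res.coverage.segments.to_csv(
                outdir / "coverage_segments.tsv", sep="\t", index=False
            )
            write_json(
                {"ac": res.coverage.ac, "chrom_bias_pct": res.coverage.chrom_bias_pct},
                outdir / "coverage_summary.json",
            )
        res.scan.fst.to_csv(outdir / "site_fst.tsv", sep="\t", index=False)
        res.scan.assoc.to_csv(outdir / "site_association.tsv", sep="\t", index=False)
        write_windows(res.scan.windows, outdir / "snp_windows.tsv")
        write_json({"candidates": res.scan.candidates}, outdir / "snp_candidates.json")
        if res.randomisation is not None:
            write_json(res.randomisation, outdir / "randomisation_report.json")
        if res.kmer_association is not None:
            res.kmer_association.drop(columns=["code"]).to_csv(
                outdir / "kmer_association.tsv", sep="\t", index=False
            )
            write_fasta(
                ((f"contig_{i}", c) for i, c in enumerate(res.contigs)),
                outdir / "kmer_contigs.fa",
            )
            if res.placements is not None:
                res.placements.to_csv(
                    outdir / "contig_placements.tsv", sep="\t", index=False
                )
                res.contigs_per_mb.to_csv(
                    outdir / "contigs_per_mb.tsv", sep="\t", index=False
                )
        if res.pattern is not None:
            res.pattern.per_snp.to_csv(
                outdir / "region_snp_patterns.tsv", sep="\t", index=False
            )
            merged = _concat_tables(
                [res.filtered.region(r["chrom"], r["start"], r["end"]) for r in res.regions],
                res.filtered,
            )
            heatmap_matrix(merged, cohort).to_csv(
                outdir / "region_heatmap.tsv", sep="\t", index=False
            )
            write_json({"regions": res.validation}, outdir / "validation_summary.json")
        write_json(res.call.to_dict(), outdir / "call.json")

        stage = "manifest"
        files = sorted(
            p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "version": __version__,
            "parameters": {
                "scan": vars(res.params),
                "filter": vars(config.filter),
                "k": config.k,
                "min_support": config.min_support,
                "min_canonical_frac": config.min_canonical_frac,
                "maf_min": config.maf_min,
                "mac_min": config.mac_min,
                "min_share": config.min_share,
                "seed": res.params.seed,
            },
            "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
        }
        write_json(manifest, outdir / "manifest.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        call=res.call,
        candidates=res.scan.candidates,
        outdir=outdir,
        manifest=manifest,
        analysis=res,
    )


def _concat_tables(tables: list[GenotypeTable], template: GenotypeTable) -> GenotypeTable:
    if not tables:
        return template.take_sites(np.empty(0, dtype=int))
    merged = GenotypeTable(
        chrom=np.concatenate([t.chrom for t in tables]),
        pos=np.concatenate([t.pos for t in tables]),
        ref=np.concatenate([t.ref for t in tables]),
        alt=np.concatenate([t.alt for t in tables]),
        qual=np.concatenate([t.qual for t in tables]),
        genotypes=np.vstack([t.genotypes for t in tables]),
        samples=list(template.samples),
        depth=None,
    ).sort()
    # overlapping regions may repeat sites; keep each site once
    if merged.n_sites:
        same = np.zeros(merged.n_sites, dtype=bool)
        same[1:] = (merged.chrom[1:] == merged.chrom[:-1]) & (
            merged.pos[1:] == merged.pos[:-1]
        )
        merged = merged.take_sites(np.flatnonzero(~same))
    return merged
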