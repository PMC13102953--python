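"""Synthetic sexed diploid cohorts with known sex-determination architecture.

The generator implants the signals the downstream scans look for, with
ground truth recorded for parameter-recovery studies:

* a recombination-suppressed sex-linked SNP block, heterozygous in the
  heterogametic sex (XY: males het, females homozygous; ZW mirrored), with
  per-individual penetrance noise;
* optional population-specific sex regions (different intervals per
  population label);
* an optional hemizygous block where the heterogametic sex carries a
  single dose, halving its pooled depth;
* a sex-limited insert present only in heterogametic-sex individuals'
  sequences (the Y/W-specific sequence channel for the k-mer scan).

Background SNPs have sex-independent allele frequencies drawn per
population from a symmetric Beta, with between-population drift as a
Beta re-draw mixed by a divergence weight. Depths are Poisson per 1 kb
window pooled by sex. Sample sequence is emitted as error-free fragments
tiled from the diploid haplotypes, densely enough that interior k-mers
occur at least twice per sample. Identical seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Sample, SexedCohort, write_sample_sheet
from .fileio import write_depth_table, write_fasta, write_json
from .variants import GenotypeTable, write_vcf

XY = "XY"
ZW = "ZW"
NONE = "NONE"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length, dtype=np.uint8)]).decode()


Region = tuple[str, int, int]  # chrom, 0-based half-open


@dataclass
class SimulationConfig:
    n_chromosomes: int = 2
    chrom_length: int = 100_000
    n_males: int = 10  # per population
    n_females: int = 10
    populations: tuple[str, ...] = ("pop1",)
    population_divergence: float = 0.0  # Beta re-draw mixing weight in [0,1]
    system: str = XY  # XY | ZW | NONE
    sex_regions: Optional[dict[str, Region]] = None  # per population; default: auto
    n_sexlinked_snps: int = 50
    penetrance: float = 1.0
    hemizygous_block: Optional[Region] = None
    sexlimited_insert_length: int = 300
    background_snp_rate: float = 0.005
    mean_depth: float = 30.0
    seed: int = 0
    read_length: int = 150
    read_step: int = 50
    base_error_rate: float = 0.0
    reference_carries_sexlimited: bool = False
    depth_window: int = 1000

    def __post_init__(self) -> None:
        if self.system not in (XY, ZW, NONE):
            raise ValueError(f"unknown system {self.system!r}")
        if min(self.n_chromosomes, self.chrom_length, self.n_males, self.n_females) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")
        if not 0.0 <= self.population_divergence <= 1.0:
            raise ValueError("population_divergence must be in [0, 1]")
        if self.system != NONE and self.sex_regions is None:
            # one shared 10 kb window-aligned region on chr1
            start = (self.chrom_length // 4 // 10_000) * 10_000
            width = min(10_000, self.chrom_length - start)
            self.sex_regions = {
                pop: ("chr1", start, start + width) for pop in self.populations
            }
        for region in list((self.sex_regions or {}).values()) + (
            [self.hemizygous_block] if self.hemizygous_block else []
        ):
            self._check_region(region)
        if self.system != NONE:
            for pop, (_, start, end) in self.sex_regions.items():
                if self.n_sexlinked_snps > end - start:
                    raise ValueError(
                        f"n_sexlinked_snps exceeds region capacity for {pop}"
                    )

    def _check_region(self, region: Region) -> None:
        chrom, start, end = region
        valid = {f"chr{i + 1}" for i in range(self.n_chromosomes)}
        if chrom not in valid:
            raise ValueError(f"region chromosome {chrom!r} outside genome")
        if not (0 <= start < end <= self.chrom_length):
            raise ValueError(f"region {region} outside chromosome bounds")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def heterogametic_sex(self) -> Optional[str]:
        return {XY: "M", ZW: "F", NONE: None}[self.system]


@dataclass
class GroundTruth:
    true_system: str
    true_regions: list[tuple[str, str, int, int]]  # (population, chrom, start, end)
    sexlimited_sequence: str
    sexlinked_site_positions: list[tuple[str, int]]  # (chrom, 1-based pos)
    insert_site: Optional[tuple[str, int]] = None  # 0-based splice point
    insert_reference_interval: Optional[tuple[str, int, int]] = None

    def to_dict(self) -> dict:
        return {
            "true_system": self.true_system,
            "true_regions": [list(r) for r in self.true_regions],
            "sexlimited_sequence": self.sexlimited_sequence,
            "sexlinked_site_positions": [list(p) for p in self.sexlinked_site_positions],
            "insert_site": list(self.insert_site) if self.insert_site else None,
            "insert_reference_interval": (
                list(self.insert_reference_interval)
                if self.insert_reference_interval
                else None
            ),
        }


@dataclass
class SimulatedData:
    config: SimulationConfig
    cohort: SexedCohort
    genotypes: GenotypeTable
    reference: dict[str, str]
    depth: pd.DataFrame
    truth: GroundTruth
    sequences: Optional[dict[str, list[str]]] = field(default=None, repr=False)


def _tile_fragments(
    seq: str, length: int, step: int, rng: np.random.Generator, error_rate: float
) -> list[str]:
    if len(seq) <= length:
        frags = [seq]
    else:
        starts = list(range(0, len(seq) - length + 1, step))
        if starts[-1] != len(seq) - length:
            starts.append(len(seq) - length)
        frags = [seq[s : s + length] for s in starts]
    if error_rate > 0:
        mutated = []
        for f in frags:
            arr = np.frombuffer(f.encode(), dtype=np.uint8).copy()
            hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
            if hits.size:
                arr[hits] = _BASES[rng.integers(0, 4, size=hits.size, dtype=np.uint8)]
            mutated.append(bytes(arr).decode())
        frags = mutated
    return frags


def simulate_cohort(
    config: SimulationConfig, with_sequences: bool = True
) -> SimulatedData:
    """Generate a cohort, genotype table, per-sample fragment sets, pooled
    depth table and ground truth from one seed."""
    rng = np.random.default_rng(config.seed)
    chroms = config.chrom_names
    L = config.chrom_length

    # cohort: per population, males then females
    samples = []
    for pop in config.populations:
        for i in range(config.n_males):
            samples.append(Sample(f"{pop}_M{i + 1:02d}", "M", pop))
        for i in range(config.n_females):
            samples.append(Sample(f"{pop}_F{i + 1:02d}", "F", pop))
    cohort = SexedCohort(samples)
    n_samples = len(cohort)
    pop_of = np.array(cohort.populations)
    sexes = cohort.sexes

    reference_base = {c: _random_seq(rng, L) for c in chroms}

    het_sex = config.heterogametic_sex

    # --- sex-linked sites ------------------------------------------------
    sexlinked: dict[str, np.ndarray] = {c: np.empty(0, dtype=np.int64) for c in chroms}
    site_pop: dict[str, dict[int, str]] = {c: {} for c in chroms}
    truth_regions: list[tuple[str, str, int, int]] = []
    if config.system != NONE:
        for pop, (chrom, start, end) in sorted(config.sex_regions.items()):
            positions = np.sort(
                rng.choice(end - start, size=config.n_sexlinked_snps, replace=False)
                + start
            )
            sexlinked[chrom] = np.union1d(sexlinked[chrom], positions)
            for p in positions:
                site_pop[chrom][int(p)] = pop
            truth_regions.append((pop, chrom, int(start), int(end)))

    follows = rng.random(n_samples) < config.penetrance

    # --- background + sex-linked genotypes per chromosome ----------------
    all_chrom, all_pos, all_ref, all_alt, all_gt = [], [], [], [], []
    for chrom in chroms:
        n_bg = rng.binomial(L, config.background_snp_rate)
        bg_pos = rng.choice(L, size=n_bg, replace=False)
        bg_pos = np.setdiff1d(bg_pos, sexlinked[chrom])
        pos = np.sort(np.concatenate([bg_pos, sexlinked[chrom]]).astype(np.int64))
        is_sexlinked = np.isin(pos, sexlinked[chrom])
        n_sites = len(pos)
        G = np.zeros((n_sites, n_samples), dtype=np.int8)

        # background: per-population Beta frequencies with divergence re-draw
        bg_idx = np.flatnonzero(~is_sexlinked)
        p0 = rng.beta(0.5, 0.5, size=len(bg_idx))
        for pop in config.populations:
            cols = np.flatnonzero(pop_of == pop)
            if config.population_divergence > 0 and len(config.populations) > 1:
                redraw = rng.beta(0.5, 0.5, size=len(bg_idx))
                p_pop = (
                    1 - config.population_divergence
                ) * p0 + config.population_divergence * redraw
            else:
                p_pop = p0
            G[np.ix_(bg_idx, cols)] = rng.binomial(
                2, p_pop[:, None], size=(len(bg_idx), len(cols))
            ).astype(np.int8)

        # sex-linked: heterogametic sex het, homogametic homozygous
        sl_idx = np.flatnonzero(is_sexlinked)
        hom_class = rng.choice(np.array([0, 2], dtype=np.int8), size=len(sl_idx))
        for row, i in enumerate(sl_idx):
            pop = site_pop[chrom][int(pos[i])]
            in_pop = pop_of == pop
            het_mask = (sexes == het_sex) == follows  # follows XOR homogametic
            codes = np.where(het_mask, np.int8(1), hom_class[row])
            G[i] = np.where(in_pop, codes, hom_class[row])

        # ref/alt from the reference base; alt any other base
        ref_bases = np.array([reference_base[chrom][p] for p in pos], dtype=object)
        alt_choices = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
        alt_bases = np.array(
            [alt_choices[b][rng.integers(0, 3)] for b in ref_bases], dtype=object
        )
        all_chrom.append(np.full(n_sites, chrom, dtype=object))
        all_pos.append(pos + 1)  # to 1-based
        all_ref.append(ref_bases)
        all_alt.append(alt_bases)
        all_gt.append(G)

    genotypes = GenotypeTable(
        chrom=np.concatenate(all_chrom),
        pos=np.concatenate(all_pos),
        ref=np.concatenate(all_ref),
        alt=np.concatenate(all_alt),
        qual=rng.uniform(50, 1000, size=sum(len(p) for p in all_pos)),
        genotypes=np.vstack(all_gt),
        samples=list(cohort.ids),
        depth=rng.poisson(
            config.mean_depth, size=(sum(len(p) for p in all_pos), n_samples)
        ).astype(np.int32),
    ).sort()

    # --- pooled depth table ----------------------------------------------
    w = config.depth_window
    n_m_total = int((sexes == "M").sum())
    n_f_total = int((sexes == "F").sum())
    rows = []
    for chrom in chroms:
        starts = np.arange(0, L, w)
        ends = np.minimum(starts + w, L)
        frac_hemi = np.zeros(len(starts))
        if config.hemizygous_block and config.hemizygous_block[0] == chrom:
            _, b0, b1 = config.hemizygous_block
            overlap = np.minimum(ends, b1) - np.maximum(starts, b0)
            frac_hemi = np.clip(overlap, 0, None) / (ends - starts)
        for sex_label, n_pool in (("m", n_m_total), ("f", n_f_total)):
            dose = (
                1.0 - 0.5 * frac_hemi
                if (het_sex is not None and sex_label == het_sex.lower())
                else np.ones(len(starts))
            )
            lam = n_pool * config.mean_depth * dose * (ends - starts)
            pooled = rng.poisson(lam) / (ends - starts)
            if sex_label == "m":
                male_depth = pooled
            else:
                female_depth = pooled
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "pooled_male_depth": male_depth,
                    "pooled_female_depth": female_depth,
                }
            )
        )
    depth = pd.concat(rows, ignore_index=True)

    # --- sex-limited insert and reference --------------------------------
    insert_seq = ""
    insert_site = None
    insert_ref_interval = None
    reference = dict(reference_base)
    if config.system != NONE and config.sexlimited_insert_length > 0:
        insert_seq = _random_seq(rng, config.sexlimited_insert_length)
        first_pop = sorted(config.sex_regions)[0]
        ins_chrom, r0, r1 = config.sex_regions[first_pop]
        ins_pos = (r0 + r1) // 2
        insert_site = (ins_chrom, int(ins_pos))
        if config.reference_carries_sexlimited:
            base = reference_base[ins_chrom]
            reference[ins_chrom] = base[:ins_pos] + insert_seq + base[ins_pos:]
            insert_ref_interval = (
                ins_chrom,
                int(ins_pos),
                int(ins_pos + len(insert_seq)),
            )

    # --- per-sample fragment sets ----------------------------------------
    sequences: Optional[dict[str, list[str]]] = None
    if with_sequences:
        sequences = {}
        plain = [reference_base[c] for c in chroms]
        carrier_hap = None
        if insert_seq:
            ins_chrom, ins_pos = insert_site
            base = reference_base[ins_chrom]
            spliced = base[:ins_pos] + insert_seq + base[ins_pos:]
            carrier_hap = [
                spliced if c == ins_chrom else reference_base[c] for c in chroms
            ]
        for s in cohort:
            hap1 = plain
            hap2 = carrier_hap if (insert_seq and s.sex == het_sex) else plain
            frags: list[str] = []
            for hap in (hap1, hap2):
                for seq in hap:
                    frags.extend(
                        _tile_fragments(
                            seq,
                            config.read_length,
                            config.read_step,
                            rng,
                            config.base_error_rate,
                        )
                    )
            sequences[s.id] = frags

    truth = GroundTruth(
        true_system=config.system,
        true_regions=truth_regions,
        sexlimited_sequence=insert_seq,
        sexlinked_site_positions=sorted(
            (c, int(p) + 1) for c in chroms for p in sexlinked[c]
        ),
        insert_site=insert_site,
        insert_reference_interval=insert_ref_interval,
    )
    return SimulatedData(
        config=config,
        cohort=cohort,
        genotypes=genotypes,
        reference=reference,
        depth=depth,
        truth=truth,
        sequences=sequences,
    )


def write_simulation(sim: SimulatedData, outdir: str | Path) -> dict[str, str]:
    """Write all simulator outputs (sample sheet, VCF, FASTAs, depth TSV,
    ground-truth JSON) under ``outdir``; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sample_sheet": str(outdir / "samples.tsv"),
        "vcf": str(outdir / "variants.vcf"),
        "reference": str(outdir / "reference.fa"),
        "depth": str(outdir / "depth.tsv"),
        "truth": str(outdir / "truth.json"),
        "sequences_dir": str(outdir / "seqs"),
    }
    write_sample_sheet(sim.cohort, paths["sample_sheet"])
    write_vcf(sim.genotypes, paths["vcf"])
    write_fasta(sim.reference, paths["reference"])
    write_depth_table(sim.depth, paths["depth"])
    write_json(sim.truth.to_dict(), paths["truth"])
    if sim.sequences is not None:
        seq_dir = Path(paths["sequences_dir"])
        seq_dir.mkdir(exist_ok=True)
        for sid, frags in sim.sequences.items():
            write_fasta(
                ((f"{sid}_frag{i}", f) for i, f in enumerate(frags)),
                seq_dir / f"{sid}.fa",
            )
    return paths
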