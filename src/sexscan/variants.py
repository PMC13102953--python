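"""Genotype tables, VCF input/output, and variant quality filtering.

Genotypes are stored as a sites × samples matrix of small integer codes:

====  =======================
code  meaning
====  =======================
0     homozygous reference
1     heterozygous
2     homozygous alternate
-1    missing
====  =======================

Positions are 1-based as in VCF; window arithmetic elsewhere converts to
0-based half-open coordinates. Phased separators are accepted on input and
treated as unphased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .cohort import SexedCohort

log = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeTable:
    """Biallelic-variant × sample genotype codes with site metadata."""

    chrom: np.ndarray  # str array, n_sites
    pos: np.ndarray  # int array, 1-based
    ref: np.ndarray  # str array
    alt: np.ndarray  # str array (comma-joined if multiallelic on input)
    qual: np.ndarray  # float array
    genotypes: np.ndarray  # int8 (n_sites, n_samples)
    samples: list[str]
    depth: Optional[np.ndarray] = None  # int (n_sites, n_samples) or None

    def __post_init__(self) -> None:
        n = len(self.pos)
        for name in ("chrom", "ref", "alt", "qual"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if self.genotypes.shape != (n, len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        if self.depth is not None and self.depth.shape != self.genotypes.shape:
            raise ValueError("depth matrix shape mismatch")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take_sites(self, idx: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            qual=self.qual[idx],
            genotypes=self.genotypes[idx],
            samples=list(self.samples),
            depth=None if self.depth is None else self.depth[idx],
        )

    def region(self, chrom: str, start: int, end: int) -> "GenotypeTable":
        """Sites with 0-based half-open interval [start, end) on ``chrom``."""
        zero_based = self.pos - 1
        mask = (self.chrom == chrom) & (zero_based >= start) & (zero_based < end)
        return self.take_sites(np.flatnonzero(mask))

    def sort(self) -> "GenotypeTable":
        order = np.lexsort((self.pos, self.chrom))
        return self.take_sites(order)


@dataclass
class VariantFilterSpec:
    """Site/genotype quality filter.

    Defaults: QUAL ≥ 30, per-genotype depth within [10, 200] (out-of-range
    calls set missing before the missingness test), indels excluded, at most
    10% missing genotypes per site. ``depth_mode`` selects whether the depth
    bound applies per genotype (default) or to the site-mean depth.
    """

    min_qual: float = 30.0
    min_depth: int = 10
    max_depth: int = 200
    exclude_indels: bool = True
    max_missing_fraction: float = 0.10
    depth_mode: str = "genotype"  # "genotype" | "site-mean"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must not exceed max_depth")
        if self.depth_mode not in ("genotype", "site-mean"):
            raise ValueError(f"unknown depth_mode {self.depth_mode!r}")


@dataclass
class FilterReport:
    n_input: int = 0
    n_qual_fail: int = 0
    n_indel: int = 0
    n_multiallelic: int = 0
    n_missing_fail: int = 0
    n_retained: int = 0
    n_genotypes_depth_masked: int = 0
    depth_applied: bool = False


def filter_variants(
    g: GenotypeTable, spec: VariantFilterSpec | None = None
) -> tuple[GenotypeTable, FilterReport]:
    """Apply the variant-quality filter and return the table plus counts.

    Order of operations: multiallelic and indel sites are dropped, then
    low-QUAL sites, then genotypes with out-of-range depth are set missing,
    and finally sites exceeding the missingness bound are dropped. Applying
    the filter twice gives the same result as applying it once.
    """
    if spec is None:
        spec = VariantFilterSpec()
    rep = FilterReport(n_input=g.n_sites)

    keep = np.ones(g.n_sites, dtype=bool)

    multi = np.char.find(g.alt.astype(str), ",") >= 0
    rep.n_multiallelic = int((keep & multi).sum())
    keep &= ~multi

    if spec.exclude_indels:
        ref_len = np.char.str_len(g.ref.astype(str))
        alt_len = np.char.str_len(g.alt.astype(str))
        indel = (ref_len != 1) | (alt_len != 1)
        rep.n_indel = int((keep & indel).sum())
        keep &= ~indel

    qual_fail = ~(g.qual >= spec.min_qual)
    rep.n_qual_fail = int((keep & qual_fail).sum())
    keep &= ~qual_fail

    genotypes = g.genotypes.copy()
    depth = g.depth
    if depth is not None:
        rep.depth_applied = True
        if spec.depth_mode == "genotype":
            bad = (depth < spec.min_depth) | (depth > spec.max_depth)
            masked = bad & (genotypes != MISSING)
            rep.n_genotypes_depth_masked = int(masked[keep].sum())
            genotypes[bad] = MISSING
        else:  # site-mean: drop whole sites with out-of-range mean depth
            called = genotypes != MISSING
            with np.errstate(invalid="ignore"):
                mean_dp = np.where(
                    called.any(axis=1),
                    np.where(called, depth, 0).sum(axis=1) / called.sum(axis=1),
                    np.nan,
                )
            bad_site = ~(
                (mean_dp >= spec.min_depth) & (mean_dp <= spec.max_depth)
            )
            keep &= ~bad_site
    else:
        log.info("no DP field present; depth rule skipped")

    missing_frac = (genotypes == MISSING).mean(axis=1)
    miss_fail = missing_frac > spec.max_missing_fraction
    rep.n_missing_fail = int((keep & miss_fail).sum())
    keep &= ~miss_fail

    out = GenotypeTable(
        chrom=g.chrom[keep],
        pos=g.pos[keep],
        ref=g.ref[keep],
        alt=g.alt[keep],
        qual=g.qual[keep],
        genotypes=genotypes[keep],
        samples=list(g.samples),
        depth=None if depth is None else depth[keep],
    )
    rep.n_retained = out.n_sites
    return out, rep


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, cohort: SexedCohort) -> GenotypeTable:
    """Read a VCF with GT (and optional DP) into a GenotypeTable.

    Samples are reordered to cohort order; the VCF sample set must match
    the cohort exactly. Non-diploid genotypes raise.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    vcf_samples = list(vcf.samples)
    extra = [s for s in vcf_samples if s not in set(cohort.ids)]
    missing = [s for s in cohort.ids if s not in set(vcf_samples)]
    if missing:
        raise ValueError(f"cohort samples absent from VCF: {missing}")
    if extra:
        raise ValueError(f"VCF samples absent from the sample sheet: {extra}")
    order = [vcf_samples.index(s) for s in cohort.ids]

    chroms, poss, refs, alts, quals = [], [], [], [], []
    gt_rows: list[list[int]] = []
    dp_rows: list[np.ndarray] = []
    have_dp = True
    for v in vcf:
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(",".join(v.ALT) if v.ALT else ".")
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        row = []
        for ci, j in enumerate(order):
            call = v.genotypes[j]
            if len(call) != 3:
                raise ValueError(
                    f"non-diploid genotype for sample {cohort.ids[ci]} "
                    f"at {v.CHROM}:{v.POS}"
                )
            a, b = call[0], call[1]
            if a < 0 or b < 0:
                row.append(MISSING)
            elif a == 0 and b == 0:
                row.append(0)
            elif a == b:
                row.append(2)
            else:
                row.append(1)
        gt_rows.append(row)
        if have_dp:
            try:
                dp = v.format("DP")
            except KeyError:  # DP absent from the FORMAT header
                dp = None
            if dp is None:
                have_dp = False
            else:
                dp_rows.append(np.asarray(dp).reshape(-1)[order])
    vcf.close()

    n = len(poss)
    genotypes = (
        np.asarray(gt_rows, dtype=np.int8)
        if n
        else np.empty((0, len(cohort)), dtype=np.int8)
    )
    depth = None
    if have_dp and dp_rows:
        depth = np.vstack(dp_rows).astype(np.int32)
        depth[depth < 0] = 0  # cyvcf2 encodes missing DP as negative sentinel
    return GenotypeTable(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        qual=np.asarray(quals, dtype=float),
        genotypes=genotypes,
        samples=list(cohort.ids),
        depth=depth,
    )


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeTable, path: str | Path) -> None:
    """Write a minimal, deterministic VCF v4.2 (GT, optional DP)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if g.depth is not None:
            fh.write(
                '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
            )
        for c in dict.fromkeys(g.chrom.tolist()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        fmt = "GT" if g.depth is None else "GT:DP"
        for i in range(g.n_sites):
            qual = g.qual[i]
            qual_s = "." if np.isnan(qual) else f"{qual:g}"
            if g.depth is None:
                calls = [_GT_STRINGS[int(c)] for c in g.genotypes[i]]
            else:
                calls = [
                    f"{_GT_STRINGS[int(c)]}:{int(d)}"
                    for c, d in zip(g.genotypes[i], g.depth[i])
                ]
            fh.write(
                f"{g.chrom[i]}\t{g.pos[i]}\t.\t{g.ref[i]}\t{g.alt[i]}\t"
                f"{qual_s}\t.\t.\t{fmt}\t" + "\t".join(calls) + "\n"
            )
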