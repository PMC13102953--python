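"""Validation of candidate sex-associated regions.

Two complementary checks on the SNPs of a candidate region:

* genotype-pattern classification: per SNP, the fraction of heterozygous
  males/females and homozygous males/females; a SNP supports an XY pattern
  when ≥50% of males are heterozygous and ≥50% of females homozygous, and a
  ZW pattern under the mirror condition;
* classical (Torgerson) multidimensional scaling of an allele-sharing
  distance matrix, with sex-concordance counted from the sign of the first
  axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SexedCohort
from .variants import GenotypeTable


@dataclass
class GenotypePatternSummary:
    per_snp: pd.DataFrame  # chrom,pos,het_frac_m,het_frac_f,hom_frac_m,hom_frac_f,xy_pattern,zw_pattern
    n_snps: int
    n_xy_pattern: int
    n_zw_pattern: int
    threshold: float

    @property
    def empty(self) -> bool:
        return self.n_snps == 0


def genotype_pattern(
    g: GenotypeTable, cohort: SexedCohort, threshold: float = 0.5
) -> GenotypePatternSummary:
    """Classify each SNP of a region by its sex-genotype pattern.

    Fractions are over non-missing calls; homozygosity counts both
    hom-ref and hom-alt. A region with zero SNPs yields an empty summary
    (valid: degenerated sex-limited regions may carry no mappable SNPs).
    """
    males = cohort.male_mask()
    females = cohort.female_mask()
    G = g.genotypes
    frames = {}
    for label, mask in (("m", males), ("f", females)):
        sub = G[:, mask]
        called = (sub >= 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            het = (sub == 1).sum(axis=1) / called
            hom = ((sub == 0) | (sub == 2)).sum(axis=1) / called
        frames[f"het_frac_{label}"] = np.where(called > 0, het, np.nan)
        frames[f"hom_frac_{label}"] = np.where(called > 0, hom, np.nan)
    per_snp = pd.DataFrame(
        {"chrom": g.chrom.astype(str), "pos": g.pos, **frames}
    )
    xy = (per_snp["het_frac_m"] >= threshold) & (per_snp["hom_frac_f"] >= threshold)
    zw = (per_snp["het_frac_f"] >= threshold) & (per_snp["hom_frac_m"] >= threshold)
    per_snp["xy_pattern"] = xy.fillna(False)
    per_snp["zw_pattern"] = zw.fillna(False)
    n_both = int((per_snp["xy_pattern"] & per_snp["zw_pattern"]).sum())
    if n_both:
        warnings.warn(f"{n_both} SNPs meet both XY and ZW thresholds", stacklevel=2)
    return GenotypePatternSummary(
        per_snp=per_snp,
        n_snps=g.n_sites,
        n_xy_pattern=int(per_snp["xy_pattern"].sum()),
        n_zw_pattern=int(per_snp["zw_pattern"].sum()),
        threshold=threshold,
    )


def heatmap_matrix(g: GenotypeTable, cohort: SexedCohort) -> pd.DataFrame:
    """Genotype matrix ordered by sex then sample id, ready for heatmap
    export (rows = samples, columns = chrom:pos, values = codes)."""
    order = sorted(range(len(cohort)), key=lambda i: (cohort.samples[i].sex, cohort.ids[i]))
    cols = [f"{c}:{p}" for c, p in zip(g.chrom, g.pos)]
    df = pd.DataFrame(g.genotypes[:, order].T, columns=cols)
    df.insert(0, "sample_id", [cohort.ids[i] for i in order])
    df.insert(1, "sex", [cohort.samples[i].sex for i in order])
    return df


def genotype_distance(g: GenotypeTable, cohort: SexedCohort) -> np.ndarray:
    """Pairwise allele-sharing distance: mean over sites non-missing in
    both samples of |code_i − code_j| / 2. Pairs with no shared sites get
    NaN."""
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    G = g.genotypes.astype(float)
    called = G >= 0
    Gz = np.where(called, G, 0.0)
    n = g.n_samples
    # shared-site counts and absolute-difference sums via matrix products
    shared = called.T.astype(float) @ called.astype(float)
    # |a-b| for codes in {0,1,2}: |a-b| = a+b-2*min(a,b); easier elementwise per pair
    dist = np.zeros((n, n))
    for i in range(n):
        both = called[:, i][:, None] & called
        diff = np.abs(Gz[:, i][:, None] - Gz) / 2.0
        diff[~both] = 0.0
        dist[i] = diff.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(shared > 0, dist / shared, np.nan)
    np.fill_diagonal(dist, 0.0)
    return dist


@dataclass
class MdsResult:
    coords: np.ndarray  # (n_samples, dims)
    eigenvalues: np.ndarray  # decreasing, length dims
    samples: list[str] = field(default_factory=list)

    def concordance(self, cohort: SexedCohort, axis: int = 0) -> dict[str, tuple[int, int]]:
        """Per sex, how many samples sit on their sex's majority side of
        the given axis. Invariant to the sign of the axis."""
        x = self.coords[:, axis]
        out = {}
        for sex in ("M", "F"):
            mask = cohort.sexes == sex
            if not mask.any():
                out[sex] = (0, 0)
                continue
            signs = np.sign(x[mask])
            pos = int((signs > 0).sum())
            neg = int((signs < 0).sum())
            out[sex] = (max(pos, neg), int(mask.sum()))
        return out


def classical_mds(
    dist: np.ndarray, dims: int = 2, samples: list[str] | None = None
) -> MdsResult:
    """Torgerson scaling: double-centre the squared distances, eigendecompose,
    and scale the top eigenvectors by √eigenvalue.

    Negative eigenvalues are dropped with a warning (their axes get zero
    coordinates). Sign convention: each axis is oriented so its first
    nonzero sample coordinate is positive.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains missing entries")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order][:dims]
    eigvec = eigvec[:, order][:, :dims]
    coords = np.zeros((n, dims))
    for a in range(min(dims, len(eigval))):
        lam = eigval[a]
        if lam > 0:
            coords[:, a] = eigvec[:, a] * np.sqrt(lam)
        elif lam < -1e-9 * max(1.0, abs(eigval[0])):
            warnings.warn(
                f"dropping negative eigenvalue {lam:.3g} on axis {a}", stacklevel=2
            )
        # orient axis: first nonzero coordinate positive
        nz = np.flatnonzero(np.abs(coords[:, a]) > 1e-12)
        if nz.size and coords[nz[0], a] < 0:
            coords[:, a] = -coords[:, a]
    return MdsResult(coords=coords, eigenvalues=eigval, samples=samples or [])
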