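"""Four-statistic SNP scan for sex-linked regions.

The scan conditions every statistic on phenotypic sex:

* per-site intersex F_ST (Weir–Cockerham 1984 two-group θ̂ from variance
  components a, b, c),
* per-sex SNP density in fixed windows, with a sex-label permutation test,
* per-sex nucleotide diversity π in the same windows,
* a 1-df allelic χ² test of SNP × sex association.

Windows enriched for the top fraction of sites in all four statistics are
integrated into candidate sex-associated regions, and a sex-label
randomisation control re-runs the integration on shuffled labels to check
that candidates depend on the true sexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .cohort import SexedCohort
from .variants import GenotypeTable

DEFAULT_WINDOW = 10_000

#: default integration depth as a fraction of windows scanned: 100 top
#: windows against a genome-scale scan of ~92,000 ten-kb windows
TOP_K_GENOME_FRACTION = 100 / 91_973


@dataclass
class ScanParameters:
    window: int = DEFAULT_WINDOW
    top_fraction: float = 0.05
    n_perm: int = 100_000
    alpha: float = 0.05
    top_k: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def scaled_top_k(n_windows: int, fraction: float = TOP_K_GENOME_FRACTION) -> int:
    """Integration depth proportional to the number of windows scanned.

    Keeps the top-window intersection selective when the genome is much
    smaller than a full assembly (where the default depth of 100 windows
    corresponds to ~0.1% of all windows).
    """
    return max(1, round(n_windows * fraction))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _sex_masks(g: GenotypeTable, cohort: SexedCohort) -> tuple[np.ndarray, np.ndarray]:
    if list(cohort.ids) != list(g.samples):
        raise ValueError("cohort and genotype table sample order mismatch")
    cohort.require_both_sexes()
    return cohort.male_mask(), cohort.female_mask()


def _allele_counts(G: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (non-missing individuals, alt allele count, het count) in subset."""
    sub = G[:, mask]
    called = sub >= 0
    n_ind = called.sum(axis=1)
    alt = np.where(called, sub, 0).sum(axis=1)
    het = (sub == 1).sum(axis=1)
    return n_ind, alt, het


def window_starts(pos: np.ndarray, w: int) -> np.ndarray:
    """0-anchored window start for each 1-based position."""
    return ((pos - 1) // w) * w


def _window_frame(g: GenotypeTable, w: int) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Unique windows containing ≥1 site, plus reduceat boundaries.

    Assumes the table is sorted by (chrom, pos); returns (frame, starts_idx,
    site_window_id).
    """
    ws = window_starts(g.pos, w)
    keys = pd.DataFrame({"chrom": g.chrom.astype(str), "start": ws})
    change = np.ones(len(ws), dtype=bool)
    if len(ws) > 1:
        change[1:] = (keys["chrom"].values[1:] != keys["chrom"].values[:-1]) | (
            ws[1:] != ws[:-1]
        )
    starts_idx = np.flatnonzero(change)
    frame = keys.iloc[starts_idx].reset_index(drop=True)
    frame["end"] = frame["start"] + w
    site_window_id = np.cumsum(change) - 1
    return frame, starts_idx, site_window_id


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------

def site_fst(g: GenotypeTable, cohort: SexedCohort) -> pd.DataFrame:
    """Weir–Cockerham per-site θ̂ between the sexes.

    Returns chrom, pos and the variance components: ``a`` (between sexes),
    ``b`` (between individuals within sex), ``c`` (within individuals), with
    θ̂ = a/(a+b+c). Sites where either sex has fewer than two non-missing
    calls, or where a+b+c = 0 (monomorphic), are flagged undefined
    (θ̂ = NaN), not zero.
    """
    males, females = _sex_masks(g, cohort)
    G = g.genotypes
    n1, alt1, het1 = _allele_counts(G, males)
    n2, alt2, het2 = _allele_counts(G, females)

    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = alt1 / (2 * n1)
        p2 = alt2 / (2 * n2)
        h1 = het1 / n1
        h2 = het2 / n2

        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        denom = a + b + c
        theta = np.where(ok & (denom != 0), a / np.where(denom == 0, np.nan, denom), np.nan)

    defined = ok & (denom != 0)
    return pd.DataFrame(
        {
            "chrom": g.chrom.astype(str),
            "pos": g.pos,
            "a": np.where(ok, a, np.nan),
            "b": np.where(ok, b, np.nan),
            "c": np.where(ok, c, np.nan),
            "theta": theta,
            "defined": defined,
        }
    )


def sex_association(g: GenotypeTable, cohort: SexedCohort) -> pd.DataFrame:
    """Allelic 1-df χ² test of sex association per site.

    Genotypes contribute alleles (hom-ref → 2 ref, het → 1+1, hom-alt →
    2 alt) to a 2×2 allele × sex table; Pearson χ² without continuity
    correction, p from the 1-df upper tail. Degenerate tables (any zero
    margin) get χ² = 0, p = 1.
    """
    males, females = _sex_masks(g, cohort)
    G = g.genotypes
    n_m, alt_m, _ = _allele_counts(G, males)
    n_f, alt_f, _ = _allele_counts(G, females)
    ref_m = 2 * n_m - alt_m
    ref_f = 2 * n_f - alt_f

    n_tot = ref_m + alt_m + ref_f + alt_f
    row_m = ref_m + alt_m
    row_f = ref_f + alt_f
    col_ref = ref_m + ref_f
    col_alt = alt_m + alt_f
    denom = row_m * row_f * col_ref * col_alt
    ok = denom > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(
            ok,
            n_tot
            * (ref_m.astype(float) * alt_f - alt_m.astype(float) * ref_f) ** 2
            / np.where(ok, denom, 1),
            0.0,
        )
    p = np.where(ok, chi2_dist.sf(chi2, df=1), 1.0)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    return pd.DataFrame(
        {
            "chrom": g.chrom.astype(str),
            "pos": g.pos,
            "ref_m": ref_m,
            "alt_m": alt_m,
            "ref_f": ref_f,
            "alt_f": alt_f,
            "chi2": chi2,
            "p": p,
        }
    )


# ---------------------------------------------------------------------------
# window statistics
# ---------------------------------------------------------------------------

def per_sex_snp_density(
    g: GenotypeTable, cohort: SexedCohort, w: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Count sites polymorphic within each sex per window.

    A site is polymorphic within a sex when its non-missing calls in that
    sex carry at least one reference and one alternate allele (so a single
    heterozygote suffices).
    """
    males, females = _sex_masks(g, cohort)
    frame, starts_idx, _ = _window_frame(g, w)
    G = g.genotypes
    out = frame.copy()
    for label, mask in (("m", males), ("f", females)):
        n_ind, alt, _ = _allele_counts(G, mask)
        poly = (alt > 0) & (alt < 2 * n_ind)
        out[f"density_{label}"] = np.add.reduceat(poly.astype(np.int64), starts_idx)
    return out


def per_sex_pi(
    g: GenotypeTable, cohort: SexedCohort, w: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Per-window nucleotide diversity for each sex.

    Site π = 2·(j/n)·(1−j/n)·n/(n−1) over the n non-missing haplotypes of
    that sex (j = alternate allele count); window π is the site sum divided
    by the window width. Sites with n < 2 haplotypes are skipped.
    """
    males, females = _sex_masks(g, cohort)
    frame, starts_idx, _ = _window_frame(g, w)
    G = g.genotypes
    out = frame.copy()
    for label, mask in (("m", males), ("f", females)):
        n_ind, alt, _ = _allele_counts(G, mask)
        n_hap = 2 * n_ind
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = alt / n_hap
            site_pi = 2.0 * freq * (1.0 - freq) * n_hap / (n_hap - 1)
        site_pi = np.where(n_hap >= 2, site_pi, 0.0)
        out[f"pi_{label}"] = np.add.reduceat(site_pi, starts_idx) / w
    return out


def _subset_window_densities(
    G: np.ndarray,
    subset: np.ndarray,
    starts_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window within-subset and within-complement polymorphic counts for
    many subsets at once. ``subset`` is (n_samples, P) float32 indicators."""
    gpos = np.where(G >= 0, G, 0).astype(np.float32)
    called = (G >= 0).astype(np.float32)
    alt = gpos @ subset  # sites × P
    nc = called @ subset
    alt_tot = gpos.sum(axis=1, keepdims=True)
    nc_tot = called.sum(axis=1, keepdims=True)
    poly_a = (alt > 0) & (alt < 2 * nc)
    poly_b = ((alt_tot - alt) > 0) & ((alt_tot - alt) < 2 * (nc_tot - nc))
    d_a = np.add.reduceat(poly_a.astype(np.int32), starts_idx, axis=0)
    d_b = np.add.reduceat(poly_b.astype(np.int32), starts_idx, axis=0)
    return d_a, d_b


def density_permutation_test(
    g: GenotypeTable,
    cohort: SexedCohort,
    w: int = DEFAULT_WINDOW,
    n_perm: int = 100_000,
    seed: int = 0,
    exhaustive: bool = False,
    chunk: int = 2048,
) -> pd.DataFrame:
    """Permutation test of the per-window density difference D = |d_M − d_F|.

    Sex labels are permuted among the sexed samples, preserving group
    sizes; the same permutation set is shared across windows. Monte-Carlo
    p-values use the add-one estimator p = (1 + #{D* ≥ D}) / (1 + N); in
    exhaustive mode every labelling (which includes the observed one) is
    enumerated and p = #{D* ≥ D} / N_total.
    """
    males, females = _sex_masks(g, cohort)
    sexed = males | females
    n_m = int(males.sum())
    sexed_idx = np.flatnonzero(sexed)

    frame, starts_idx, _ = _window_frame(g, w)
    G = g.genotypes

    obs = males.astype(np.float32)[:, None]
    d_m, d_f = _subset_window_densities(G, obs, starts_idx)
    d_obs = np.abs(d_m - d_f)[:, 0]

    if exhaustive:
        n_total = comb(len(sexed_idx), n_m)
        assignments = combinations(sexed_idx.tolist(), n_m)

        def batches():
            batch = []
            for combo in assignments:
                batch.append(combo)
                if len(batch) == chunk:
                    yield batch
                    batch = []
            if batch:
                yield batch

        count = np.zeros(len(frame), dtype=np.int64)
        for batch in batches():
            S = np.zeros((G.shape[1], len(batch)), dtype=np.float32)
            for j, combo in enumerate(batch):
                S[list(combo), j] = 1.0
            da, db = _subset_window_densities(G, S, starts_idx)
            d_star = np.abs(da - db)
            count += (d_star >= d_obs[:, None]).sum(axis=1)
        p = count / n_total
        n_reported = n_total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(frame), dtype=np.int64)
        remaining = n_perm
        while remaining > 0:
            batch = min(chunk, remaining)
            S = np.zeros((G.shape[1], batch), dtype=np.float32)
            for j in range(batch):
                S[rng.choice(sexed_idx, size=n_m, replace=False), j] = 1.0
            da, db = _subset_window_densities(G, S, starts_idx)
            d_star = np.abs(da - db)
            count += (d_star >= d_obs[:, None]).sum(axis=1)
            remaining -= batch
        p = (1 + count) / (1 + n_perm)
        n_reported = n_perm

    out = frame.copy()
    out["density_m"] = d_m[:, 0]
    out["density_f"] = d_f[:, 0]
    out["d_obs"] = d_obs
    out["p"] = p
    out.attrs["n_perm"] = n_reported
    return out


# ---------------------------------------------------------------------------
# window integration and the randomisation control
# ---------------------------------------------------------------------------

def _merge_windows(frame: pd.DataFrame) -> list[dict]:
    """Merge adjacent/overlapping candidate windows into regions."""
    regions: list[dict] = []
    for _, row in frame.sort_values(["chrom", "start"]).iterrows():
        if (
            regions
            and regions[-1]["chrom"] == row["chrom"]
            and row["start"] <= regions[-1]["end"]
        ):
            regions[-1]["end"] = max(regions[-1]["end"], int(row["end"]))
            regions[-1]["n_windows"] += 1
        else:
            regions.append(
                {
                    "chrom": str(row["chrom"]),
                    "start": int(row["start"]),
                    "end": int(row["end"]),
                    "n_windows": 1,
                }
            )
    return regions


def integrate_windows(
    fst: pd.DataFrame,
    assoc: pd.DataFrame,
    density: pd.DataFrame,
    pi: pd.DataFrame,
    params: ScanParameters,
) -> tuple[pd.DataFrame, list[dict]]:
    """Intersect the top windows of all four statistics.

    Per metric, windows are ranked: by count of globally top-``q`` θ̂ sites
    (undefined excluded); by count of top-``q`` smallest association p; by
    permutation p ≤ α then |density difference|; and by |π_M − π_F|. A
    window is a candidate when it appears in the top-``top_k`` list of all
    four metrics; adjacent candidates are merged into regions.
    """
    w = params.window
    q = params.top_fraction

    table = density.merge(pi, on=["chrom", "start", "end"], how="outer")
    table = table.sort_values(["chrom", "start"]).reset_index(drop=True)
    key = list(zip(table["chrom"], table["start"]))
    key_index = {k: i for i, k in enumerate(key)}

    def per_window_count(site_df: pd.DataFrame, top_mask: np.ndarray) -> np.ndarray:
        counts = np.zeros(len(table), dtype=np.int64)
        ws = window_starts(site_df["pos"].to_numpy(), w)
        for chrom, start in zip(site_df["chrom"].to_numpy()[top_mask], ws[top_mask]):
            i = key_index.get((chrom, start))
            if i is not None:
                counts[i] += 1
        return counts

    theta = fst["theta"].to_numpy(float)
    defined = fst["defined"].to_numpy(bool)
    if defined.any():
        thr_fst = np.quantile(theta[defined], 1 - q)
        fst_top = defined & (theta >= thr_fst)
    else:
        fst_top = np.zeros(len(fst), dtype=bool)
    table["fst_top_count"] = per_window_count(fst, fst_top)

    p_assoc = assoc["p"].to_numpy(float)
    thr_assoc = np.quantile(p_assoc, q) if len(p_assoc) else np.nan
    assoc_top = p_assoc <= thr_assoc if len(p_assoc) else np.zeros(0, bool)
    table["assoc_top_count"] = per_window_count(assoc, assoc_top)

    table["pi_diff"] = (table["pi_m"] - table["pi_f"]).abs()
    table["density_diff"] = (
        table["density_m"].astype(float) - table["density_f"].astype(float)
    ).abs()

    k = params.top_k

    def top_set(eligible: pd.Series, order_cols: list, ascending: list) -> set[int]:
        sub = table[eligible].sort_values(
            order_cols + ["chrom", "start"],
            ascending=ascending + [True, True],
            kind="mergesort",
        )
        return set(sub.index[:k])

    sets = {
        "fst": top_set(table["fst_top_count"] > 0, ["fst_top_count"], [False]),
        "assoc": top_set(table["assoc_top_count"] > 0, ["assoc_top_count"], [False]),
        "density": top_set(table["p"] <= params.alpha, ["p", "density_diff"], [True, False]),
        "pi": top_set(table["pi_diff"] > 0, ["pi_diff"], [False]),
    }
    for name, s in sets.items():
        table[f"in_top_{name}"] = table.index.isin(list(s))
    candidate_idx = set.intersection(*sets.values())
    table["candidate"] = table.index.isin(list(candidate_idx))

    regions = _merge_windows(table[table["candidate"]])
    return table, regions


@dataclass
class SnpScanResult:
    fst: pd.DataFrame
    assoc: pd.DataFrame
    windows: pd.DataFrame
    candidates: list[dict] = field(default_factory=list)
    params: ScanParameters = field(default_factory=ScanParameters)


def snp_scan(
    g: GenotypeTable, cohort: SexedCohort, params: ScanParameters | None = None
) -> SnpScanResult:
    """Run all four statistics and the window integration."""
    if params is None:
        params = ScanParameters()
    fst = site_fst(g, cohort)
    assoc = sex_association(g, cohort)
    density = density_permutation_test(
        g, cohort, w=params.window, n_perm=params.n_perm, seed=params.seed
    )
    pi = per_sex_pi(g, cohort, w=params.window)
    windows, candidates = integrate_windows(fst, assoc, density, pi, params)
    return SnpScanResult(fst=fst, assoc=assoc, windows=windows, candidates=candidates, params=params)


def randomisation_control(
    g: GenotypeTable,
    cohort: SexedCohort,
    params: ScanParameters,
    n_rounds: int = 20,
    seed: int = 0,
    original: SnpScanResult | None = None,
) -> dict:
    """Re-run the full integration on randomly re-sexed cohorts.

    Genuine sex-linked candidates should not recur when the labels are
    shuffled. The report counts, per round, the candidate windows and
    whether any window of the original candidate set reappears; the
    original signal is considered validated when the recurrence fraction
    is below ``params.alpha``.
    """
    if original is None:
        original = snp_scan(g, cohort, params)
    original_keys = {
        (row["chrom"], int(row["start"]))
        for _, row in original.windows[original.windows["candidate"]].iterrows()
    }
    rng = np.random.default_rng(seed)
    sexes = cohort.sexes
    rounds = []
    n_recur = 0
    for r in range(n_rounds):
        shuffled = sexes.copy()
        sexed = np.flatnonzero((sexes == "M") | (sexes == "F"))
        shuffled[sexed] = sexes[sexed][rng.permutation(len(sexed))]
        perm_cohort = cohort.with_sexes(shuffled)
        perm_params = ScanParameters(
            window=params.window,
            top_fraction=params.top_fraction,
            n_perm=params.n_perm,
            alpha=params.alpha,
            top_k=params.top_k,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        res = snp_scan(g, perm_cohort, perm_params)
        keys = {
            (row["chrom"], int(row["start"]))
            for _, row in res.windows[res.windows["candidate"]].iterrows()
        }
        recur = bool(keys & original_keys)
        n_recur += recur
        rounds.append(
            {
                "round": r,
                "n_candidates": len(keys),
                "candidates": sorted([f"{c}:{s}" for c, s in keys]),
                "original_recurs": recur,
            }
        )
    frac = n_recur / n_rounds if n_rounds else 0.0
    return {
        "n_rounds": n_rounds,
        "n_original_candidates": len(original_keys),
        "n_rounds_recurring": n_recur,
        "recurrence_fraction": frac,
        "validated": bool(original_keys) and frac < params.alpha,
        "rounds": rounds,
    }
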