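"""Sex-pooled coverage comparison in fixed genomic windows.

A degenerate (hemizygous) sex-chromosome region is present in one dose in
the heterogametic sex, so its pooled depth in that sex is expected to drop
to ~50% of the other sex's — an adjusted log2 depth ratio of −1. Autosomal
windows sit at 0 after normalising by the adjustment coefficient (AC), the
genome-wide ratio of male to female pooled depth, which absorbs differences
in sample number and sequencing effort between the sex pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_WINDOW = 1000


@dataclass
class CoverageScanResult:
    ac: float
    windows: pd.DataFrame  # chrom, start, end, pooled depths, score
    segments: pd.DataFrame = field(default_factory=pd.DataFrame)
    chrom_bias_pct: dict[str, float] = field(default_factory=dict)


def compute_adjusted_log2(depth: pd.DataFrame, eps: float = 0.5) -> tuple[pd.DataFrame, float]:
    """Score each window with log2((d_M + ε) / (AC · (d_F + ε))).

    AC = median male pooled depth / median female pooled depth over windows
    where both depths are positive. ε (default 0.5) keeps zero-depth
    windows finite. Raises if depths are all zero in either sex.
    """
    if eps < 0:
        raise ValueError("pseudocount must be >= 0")
    d_m = depth["pooled_male_depth"].to_numpy(float)
    d_f = depth["pooled_female_depth"].to_numpy(float)
    both = (d_m > 0) & (d_f > 0)
    if not both.any():
        raise ValueError("no window with positive depth in both sexes")
    ac = float(np.median(d_m[both]) / np.median(d_f[both]))
    with np.errstate(divide="ignore"):
        score = np.log2((d_m + eps) / (ac * (d_f + eps)))
    out = depth.copy()
    out["score"] = score
    return out, ac


def segment_scores(
    windows: pd.DataFrame, threshold: float = 1.0, min_run: int = 5
) -> pd.DataFrame:
    """Call maximal runs of ≥ ``min_run`` consecutive same-direction extreme
    windows (|score| ≥ threshold), merging runs across gaps of ≤ 1 window.

    Returns BED-style segments with mean score and direction (+/−).
    A simple deterministic stand-in for changepoint segmentation, adequate
    for block-shaped dosage signals.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    segments = []
    for chrom, sub in windows.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        scores = sub["score"].to_numpy(float)
        starts = sub["start"].to_numpy(int)
        ends = sub["end"].to_numpy(int)
        for direction, mask in (
            ("+", scores >= threshold),
            ("-", scores <= -threshold),
        ):
            hits = np.flatnonzero(mask)
            if hits.size == 0:
                continue
            # group hit indices, allowing a gap of one non-qualifying window
            breaks = np.flatnonzero(np.diff(hits) > 2)
            groups = np.split(hits, breaks + 1)
            for grp in groups:
                if grp.size < min_run:
                    continue
                lo, hi = grp[0], grp[-1]
                segments.append(
                    {
                        "chrom": chrom,
                        "start": int(starts[lo]),
                        "end": int(ends[hi]),
                        "n_windows": int(grp.size),
                        "mean_score": float(scores[grp].mean()),
                        "direction": direction,
                    }
                )
    cols = ["chrom", "start", "end", "n_windows", "mean_score", "direction"]
    if not segments:
        return pd.DataFrame(columns=cols)
    return (
        pd.DataFrame(segments, columns=cols)
        .sort_values(["chrom", "start"], kind="mergesort")
        .reset_index(drop=True)
    )


def chromosome_bias_fraction(windows: pd.DataFrame, threshold: float = 1.0) -> dict[str, float]:
    """Percentage of windows per chromosome with |score| ≥ threshold."""
    out = {}
    for chrom, sub in windows.groupby("chrom", sort=True):
        scores = sub["score"].to_numpy(float)
        out[str(chrom)] = float(100.0 * (np.abs(scores) >= threshold).mean())
    return out


def coverage_scan(
    depth: pd.DataFrame,
    eps: float = 0.5,
    threshold: float = 1.0,
    min_run: int = 5,
) -> CoverageScanResult:
    """Full coverage stage: scores, segments and per-chromosome bias."""
    windows, ac = compute_adjusted_log2(depth, eps=eps)
    segments = segment_scores(windows, threshold=threshold, min_run=min_run)
    bias = chromosome_bias_fraction(windows, threshold=threshold)
    return CoverageScanResult(ac=ac, windows=windows, segments=segments, chrom_bias_pct=bias)
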