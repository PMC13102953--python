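"""Reference-free k-mer scan for sex-specific sequence.

Canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement, k odd) are counted per sample from 2-bit-packed sequence, built
into a cohort presence/absence matrix with support, canonicality, and
minor-allele filters, tested for sex association with a 1-df allelic χ²
(each sample contributes two carrier or two non-carrier alleles), assembled
into de Bruijn unitigs, and placed on a reference by exact matching.

Counting is numpy-vectorised: windows are packed into 64-bit integers by a
logarithmic rolling concatenation, so k ≤ 31 fits a uint64 and genome-scale
inputs stream in chunks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .cohort import SexedCohort

DEFAULT_K = 31

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_RC_TABLE = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def canonical(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def encode_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer:
        v = _CODE[ord(ch)]
        if v > 3:
            raise ValueError(f"non-ACGT base in k-mer {kmer!r}")
        code = (code << 2) | int(v)
    return code


def decode_kmer(code: int, k: int) -> str:
    return "".join("ACGT"[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def _check_k(k: int) -> None:
    if not 1 < k <= 31:
        raise ValueError("k must satisfy 1 < k <= 31")
    if k % 2 == 0:
        raise ValueError("k must be odd (even k makes palindromes canonically ambiguous)")


def _rolling_pack(digits: np.ndarray, k: int) -> np.ndarray:
    """value[i] = Σ_j digits[i+j]·4^(k-1-j) for all windows, via doubling."""
    n = len(digits)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    cur = digits.astype(np.uint64)
    cur_len = 1
    result: np.ndarray | None = None
    res_len = 0
    rem = k
    while rem:
        if rem & 1:
            if result is None:
                result = cur.copy()
                res_len = cur_len
            else:
                m = n - (res_len + cur_len) + 1
                result = (result[:m] << np.uint64(2 * cur_len)) + cur[res_len : res_len + m]
                res_len += cur_len
        rem >>= 1
        if rem:
            m2 = n - 2 * cur_len + 1
            cur = (cur[:m2] << np.uint64(2 * cur_len)) + cur[cur_len : cur_len + m2]
            cur_len *= 2
    assert result is not None and res_len == k
    return result


def sequence_codes(seq: str, k: int) -> np.ndarray:
    """Canonical k-mer codes of every window of ``seq``; windows containing
    non-ACGT characters (e.g. N) are skipped."""
    _check_k(k)
    b = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n_win = len(b) - k + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.uint64)
    bad = (b > 3).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    clean = np.where(b > 3, 0, b)
    fwd = _rolling_pack(clean, k)
    rc_all = _rolling_pack((3 - clean)[::-1], k)[::-1]
    can = np.minimum(fwd, rc_all)
    return can[valid]


@dataclass
class KmerCountTable:
    """Canonical k-mer → count for one sample."""

    k: int
    codes: np.ndarray  # sorted unique uint64
    counts: np.ndarray  # int64, same length

    def __len__(self) -> int:
        return len(self.codes)

    def get(self, kmer: str) -> int:
        code = np.uint64(encode_kmer(canonical(kmer)))
        i = np.searchsorted(self.codes, code)
        if i < len(self.codes) and self.codes[i] == code:
            return int(self.counts[i])
        return 0

    def to_counter(self) -> Counter:
        return Counter(
            {decode_kmer(int(c), self.k): int(n) for c, n in zip(self.codes, self.counts)}
        )


def count_kmers(seqs: str | Iterable[str], k: int = DEFAULT_K) -> KmerCountTable:
    """Count canonical k-mers over one or many sequences (reads or contigs).

    Sequences are processed in chunks joined by N separators, so k-mers
    never span sequence boundaries.
    """
    _check_k(k)
    if isinstance(seqs, str):
        seqs = [seqs]
    parts: list[np.ndarray] = []
    buffer: list[str] = []
    size = 0
    for s in seqs:
        buffer.append(s)
        size += len(s) + 1
        if size >= 4_000_000:
            parts.append(sequence_codes("N".join(buffer), k))
            buffer, size = [], 0
    if buffer:
        parts.append(sequence_codes("N".join(buffer), k))
    allcodes = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint64)
    codes, counts = np.unique(allcodes, return_counts=True)
    return KmerCountTable(k=k, codes=codes, counts=counts.astype(np.int64))


# ---------------------------------------------------------------------------
# presence/absence matrix
# ---------------------------------------------------------------------------

@dataclass
class KmerMatrix:
    """Canonical k-mer × sample presence/absence with the cohort filters."""

    k: int
    codes: np.ndarray  # sorted uint64
    samples: list[str]
    presence: np.ndarray  # bool (n_kmers, n_samples); count >= 1
    count_ge2: np.ndarray  # bool, same shape; k-mer canonical in that sample

    @property
    def n_kmers(self) -> int:
        return len(self.codes)

    @property
    def support(self) -> np.ndarray:
        return self.presence.sum(axis=1)

    @property
    def canonical_fraction(self) -> np.ndarray:
        """Fraction of *present* samples in which the k-mer has count ≥ 2."""
        sup = self.support
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = (self.count_ge2 & self.presence).sum(axis=1) / sup
        return np.where(sup > 0, frac, 0.0)

    @property
    def mac(self) -> np.ndarray:
        """Minor allele count over carrier status (one allele per sample)."""
        sup = self.support
        return np.minimum(sup, len(self.samples) - sup)

    @property
    def maf(self) -> np.ndarray:
        return self.mac / len(self.samples)

    def kmer_strings(self) -> list[str]:
        return [decode_kmer(int(c), self.k) for c in self.codes]

    def take(self, mask: np.ndarray) -> "KmerMatrix":
        return replace(
            self,
            codes=self.codes[mask],
            presence=self.presence[mask],
            count_ge2=self.count_ge2[mask],
        )


def build_matrix(
    counts: Mapping[str, KmerCountTable],
    cohort: SexedCohort,
    min_support: int = 5,
    min_canonical_frac: float = 0.20,
) -> KmerMatrix:
    """Union per-sample counts into a matrix, applying the cohort filters:
    the k-mer must be present (count ≥ 1) in at least ``min_support``
    samples and have count ≥ 2 in at least ``min_canonical_frac`` of the
    samples carrying it."""
    missing = [s for s in cohort.ids if s not in counts]
    if missing:
        raise ValueError(f"no k-mer counts for samples: {missing}")
    if len(cohort) < min_support:
        raise ValueError("cohort smaller than min_support")
    ks = {t.k for t in counts.values()}
    if len(ks) != 1:
        raise ValueError("inconsistent k across samples")
    k = ks.pop()

    union = np.unique(np.concatenate([counts[s].codes for s in cohort.ids]))
    n_samples = len(cohort)
    presence = np.zeros((len(union), n_samples), dtype=bool)
    ge2 = np.zeros_like(presence)
    for j, sid in enumerate(cohort.ids):
        t = counts[sid]
        idx = np.searchsorted(union, t.codes)
        presence[idx, j] = True
        ge2[idx, j] = t.counts >= 2

    m = KmerMatrix(k=k, codes=union, samples=list(cohort.ids), presence=presence, count_ge2=ge2)
    keep = (m.support >= min_support) & (m.canonical_fraction >= min_canonical_frac)
    return m.take(keep)


def filter_maf_mac(m: KmerMatrix, maf_min: float = 0.05, mac_min: int = 5) -> KmerMatrix:
    """Keep k-mers with minor-allele frequency/count (over carrier status)
    at or above the bounds."""
    keep = (m.maf >= maf_min) & (m.mac >= mac_min)
    return m.take(keep)


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

def kmer_association(m: KmerMatrix, cohort: SexedCohort) -> pd.DataFrame:
    """Allelic χ² association of carrier status with sex.

    Carriers contribute two carrier alleles, non-carriers two non-carrier
    alleles, giving a 2×2 allele × sex table per k-mer; under perfect
    separation χ² equals the total allele count. Results are sorted by
    ascending p (ties by k-mer code). Specificity: a k-mer present in ≥1
    sample of one sex and none of the other.
    """
    if list(m.samples) != list(cohort.ids):
        raise ValueError("matrix and cohort sample order mismatch")
    cohort.require_both_sexes()
    males = cohort.male_mask()
    females = cohort.female_mask()
    n_m = int(males.sum())
    n_f = int(females.sum())
    c_m = m.presence[:, males].sum(axis=1)
    c_f = m.presence[:, females].sum(axis=1)

    a = 2.0 * c_m  # carrier alleles, males
    b = 2.0 * (n_m - c_m)
    c = 2.0 * c_f
    d = 2.0 * (n_f - c_f)
    n_tot = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    ok = denom > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(ok, n_tot * (a * d - b * c) ** 2 / np.where(ok, denom, 1.0), 0.0)
    p = np.where(ok, chi2_dist.sf(chi2, df=1), 1.0)
    p = np.clip(p, np.nextafter(0, 1), 1.0)

    specificity = np.where(
        (c_m > 0) & (c_f == 0),
        "male-specific",
        np.where((c_f > 0) & (c_m == 0), "female-specific", "shared"),
    )
    df = pd.DataFrame(
        {
            "code": m.codes,
            "kmer": m.kmer_strings(),
            "carriers_m": c_m,
            "carriers_f": c_f,
            "chi2": chi2,
            "p": p,
            "specificity": specificity,
        }
    )
    return df.sort_values(["p", "code"], kind="mergesort").reset_index(drop=True)


def top_kmers(assoc: pd.DataFrame, quantile: float | None = None) -> pd.DataFrame:
    """The significant set: all k-mers tied at the minimum p, or, when
    ``quantile`` is given, the top fraction of smallest p-values."""
    if assoc.empty:
        return assoc
    if quantile is None:
        return assoc[assoc["p"] == assoc["p"].min()].reset_index(drop=True)
    thr = assoc["p"].quantile(quantile)
    return assoc[assoc["p"] <= thr].reset_index(drop=True)


# ---------------------------------------------------------------------------
# unitig assembly
# ---------------------------------------------------------------------------

def assemble_contigs(kmers: Iterable[str], k: int | None = None) -> list[str]:
    """Assemble canonical k-mers into unitigs of their de Bruijn graph.

    Nodes are the k-mers (and implicitly their reverse complements); edges
    are (k−1)-overlaps. A unitig extends while the next k-mer is the unique
    successor and the current k-mer is its unique predecessor; extension
    stops at branches, at already-used k-mers (cycles) and at self-overlaps.
    Every input k-mer ends up in exactly one contig. Output contigs are
    canonicalised (lexicographic min of contig/revcomp) and sorted.
    """
    kset = {canonical(s) for s in kmers}
    if not kset:
        return []
    if k is None:
        k = len(next(iter(kset)))
    if any(len(s) != k for s in kset):
        raise ValueError("k-mers of mixed length")

    def successors(s: str) -> list[str]:
        out = []
        for base in "ACGT":
            t = s[1:] + base
            if canonical(t) in kset:
                out.append(t)
        return out

    def predecessors(s: str) -> list[str]:
        out = []
        for base in "ACGT":
            t = base + s[:-1]
            if canonical(t) in kset:
                out.append(t)
        return out

    visited: set[str] = set()
    contigs: list[str] = []
    for start in sorted(kset):
        if start in visited:
            continue
        used = {start}
        seq = start
        # extend right
        cur = start
        while True:
            nxt = successors(cur)
            if len(nxt) != 1:
                break
            t = nxt[0]
            ct = canonical(t)
            if ct in visited or ct in used or len(predecessors(t)) != 1:
                break
            seq += t[-1]
            used.add(ct)
            cur = t
        # extend left
        cur = start
        while True:
            prv = predecessors(cur)
            if len(prv) != 1:
                break
            t = prv[0]
            ct = canonical(t)
            if ct in visited or ct in used or len(successors(t)) != 1:
                break
            seq = t[0] + seq
            used.add(ct)
            cur = t
        visited |= used
        contigs.append(canonical(seq))
    return sorted(contigs)


# ---------------------------------------------------------------------------
# reference placement
# ---------------------------------------------------------------------------

def _find_all(haystack: str, needle: str) -> list[int]:
    hits = []
    i = haystack.find(needle)
    while i >= 0:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def place_contigs(
    contigs: Iterable[str],
    reference: Mapping[str, str],
    bin_size: int = 1_000_000,
    max_mismatch_frac: float = 0.0,
    seed_length: int = 31,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact substring placement of contigs (and reverse complements) on a
    reference, with per-Mb counts of placed contigs.

    Returns (placements, per_mb). Placements are 0-based starts with
    strand; contigs without hits get a single row with chrom NaN. When
    ``max_mismatch_frac`` > 0, a seed-and-extend fallback additionally
    reports partial hits (exact ``seed_length`` prefix/suffix seed, then
    full-length comparison tolerating that mismatch fraction).
    """
    rows = []
    for ci, contig in enumerate(contigs):
        rc = revcomp(contig)
        placed = False
        for chrom, seq in reference.items():
            for strand, query in (("+", contig), ("-", rc)):
                for start in _find_all(seq, query):
                    rows.append(
                        {
                            "contig_index": ci,
                            "contig": contig,
                            "chrom": chrom,
                            "start": start,
                            "end": start + len(contig),
                            "strand": strand,
                            "match": "exact",
                        }
                    )
                    placed = True
        if not placed and max_mismatch_frac > 0 and len(contig) >= seed_length:
            max_mm = int(max_mismatch_frac * len(contig))
            for chrom, seq in reference.items():
                for strand, query in (("+", contig), ("-", rc)):
                    seed = query[:seed_length]
                    for s in _find_all(seq, seed):
                        window = seq[s : s + len(query)]
                        if len(window) < len(query):
                            continue
                        mm = sum(1 for x, y in zip(window, query) if x != y)
                        if 0 < mm <= max_mm:
                            rows.append(
                                {
                                    "contig_index": ci,
                                    "contig": contig,
                                    "chrom": chrom,
                                    "start": s,
                                    "end": s + len(query),
                                    "strand": strand,
                                    "match": "partial",
                                }
                            )
                            placed = True
        if not placed:
            rows.append(
                {
                    "contig_index": ci,
                    "contig": contig,
                    "chrom": None,
                    "start": -1,
                    "end": -1,
                    "strand": ".",
                    "match": "unplaced",
                }
            )
    placements = pd.DataFrame(
        rows,
        columns=["contig_index", "contig", "chrom", "start", "end", "strand", "match"],
    )
    hits = placements[placements["match"] != "unplaced"]
    if hits.empty:
        per_mb = pd.DataFrame(columns=["chrom", "bin_start", "n_contigs"])
    else:
        binned = hits.assign(bin_start=(hits["start"] // bin_size) * bin_size)
        per_mb = (
            binned.groupby(["chrom", "bin_start"])["contig_index"]
            .nunique()
            .rename("n_contigs")
            .reset_index()
            .sort_values(["chrom", "bin_start"], kind="mergesort")
            .reset_index(drop=True)
        )
    return placements, per_mb
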