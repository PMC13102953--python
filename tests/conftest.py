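"""Shared fixtures: small hand-built cohorts and genotype tables."""

from __future__ import annotations

import numpy as np
import pytest

from sexscan.cohort import Sample, SexedCohort
from sexscan.variants import GenotypeTable


def make_cohort(n_males: int, n_females: int, population: str = "pop1") -> SexedCohort:
    return SexedCohort(
        [Sample(f"m{i + 1}", "M", population) for i in range(n_males)]
        + [Sample(f"f{i + 1}", "F", population) for i in range(n_females)]
    )


def make_table(
    rows,
    samples,
    chrom: str = "chr1",
    start_pos: int = 100,
    spacing: int = 100,
    qual: float = 100.0,
    depth=None,
    ref="A",
    alt="C",
) -> GenotypeTable:
    """Genotype table from a list of per-site code rows."""
    G = np.asarray(rows, dtype=np.int8)
    n = G.shape[0]
    pos = np.arange(start_pos, start_pos + n * spacing, spacing, dtype=np.int64)
    refs = np.array([ref] * n if isinstance(ref, str) else ref, dtype=object)
    alts = np.array([alt] * n if isinstance(alt, str) else alt, dtype=object)
    quals = np.full(n, qual) if np.isscalar(qual) else np.asarray(qual, dtype=float)
    return GenotypeTable(
        chrom=np.full(n, chrom, dtype=object),
        pos=pos,
        ref=refs,
        alt=alts,
        qual=quals,
        genotypes=G,
        samples=list(samples),
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
    )


@pytest.fixture
def cohort_3v3() -> SexedCohort:
    return make_cohort(3, 3)


@pytest.fixture
def cohort_13v13() -> SexedCohort:
    return make_cohort(13, 13)
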