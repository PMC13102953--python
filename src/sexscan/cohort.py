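"""Sexed sample cohorts.

A cohort is the unit every sex-conditioned scan operates on: an ordered list
of samples, each with a phenotypic sex (``M``, ``F`` or ``U`` for unknown)
and a population label (e.g. a river drainage). Sample ids must be unique;
operations that compare the sexes require at least one male and one female.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_SEXES = frozenset({"M", "F", "U"})


@dataclass(frozen=True)
class Sample:
    id: str
    sex: str  # "M", "F" or "U"
    population: str = "pop1"

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise ValueError(f"invalid sex {self.sex!r} for sample {self.id!r}")


@dataclass
class SexedCohort:
    """Ordered collection of sexed samples."""

    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def sexes(self) -> np.ndarray:
        return np.array([s.sex for s in self.samples])

    @property
    def populations(self) -> list[str]:
        return [s.population for s in self.samples]

    def male_mask(self) -> np.ndarray:
        return self.sexes == "M"

    def female_mask(self) -> np.ndarray:
        return self.sexes == "F"

    def require_both_sexes(self) -> None:
        if not self.male_mask().any() or not self.female_mask().any():
            raise ValueError("cohort must contain at least one male and one female")

    def subset(self, ids: Sequence[str]) -> "SexedCohort":
        wanted = set(ids)
        return SexedCohort([s for s in self.samples if s.id in wanted])

    def with_sexes(self, sexes: Iterable[str]) -> "SexedCohort":
        """Return a copy with the per-sample sexes replaced (used by label
        permutation / randomisation controls)."""
        sexes = list(sexes)
        if len(sexes) != len(self.samples):
            raise ValueError("sex vector length mismatch")
        return SexedCohort(
            [Sample(s.id, x, s.population) for s, x in zip(self.samples, sexes)]
        )

    # -- sample sheet I/O ------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SexedCohort":
        required = {"sample_id", "sex", "population"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        return cls(
            [
                Sample(str(r.sample_id), str(r.sex), str(r.population))
                for r in df.itertuples()
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.ids,
                "sex": [s.sex for s in self.samples],
                "population": self.populations,
            }
        )


def read_sample_sheet(path: str | Path) -> SexedCohort:
    """Read a TSV sample sheet with columns sample_id, sex, population."""
    return SexedCohort.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_sheet(cohort: SexedCohort, path: str | Path) -> None:
    cohort.to_frame().to_csv(path, sep="\t", index=False)
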