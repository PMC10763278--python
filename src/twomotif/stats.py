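"""Group comparison of P3A (PM H+-ATPase) copy numbers.

Compares salt-tolerant (halophyte) and salt-sensitive (glycophyte) diploid
species on pump copy number — raw and normalised by protein-coding gene count
— using group means with SEM and a pooled two-sided Student's t-test.  The
packaged survey table ships with the package; any TSV with the same schema
(species, group, protein_coding_genes, p3a_count) can be analysed.

The t statistic is computed from the textbook pooled-variance formula

    t = (x̄₁ − x̄₂) / √(s_p² (1/n₁ + 1/n₂)),
    s_p² = ((n₁−1)s₁² + (n₂−1)s₂²) / (n₁ + n₂ − 2),

with the two-sided p-value from the t distribution on n₁+n₂−2 df.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from scipy.stats import t as t_dist

__all__ = [
    "SpeciesRecord",
    "GroupSummary",
    "GroupComparison",
    "DegenerateVarianceError",
    "load_species_table",
    "packaged_survey_path",
    "group_summary",
    "two_sample_t",
    "compare_groups",
]

GLYCOPHYTE = "glycophyte"
HALOPHYTE = "halophyte"


class DegenerateVarianceError(ValueError):
    """Raised when both groups have zero variance but unequal means."""


@dataclass(frozen=True)
class SpeciesRecord:
    species: str
    group: str
    protein_coding_genes: int
    p3a_count: int

    def __post_init__(self) -> None:
        if self.protein_coding_genes <= 0 or self.p3a_count <= 0:
            raise ValueError(f"{self.species}: counts must be positive")

    @property
    def ratio(self) -> float:
        """Pump copies per protein-coding gene (always recomputed)."""
        return self.p3a_count / self.protein_coding_genes


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and (for n >= 2) sample SD and SEM = SD/sqrt(n)."""

    n: int
    mean: float
    sd: float | None
    sem: float | None


@dataclass(frozen=True)
class GroupComparison:
    group_a: GroupSummary
    group_b: GroupSummary
    t: float
    df: int
    p: float


def packaged_survey_path():
    """Path to the packaged species survey TSV."""
    return resources.files("twomotif") / "data" / "p3a_halophyte_survey.tsv"


def load_species_table(path=None) -> list[SpeciesRecord]:
    """Read a species table TSV; defaults to the packaged survey."""
    frame = pd.read_csv(str(path or packaged_survey_path()), sep="\t")
    required = {"species", "group", "protein_coding_genes", "p3a_count"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"species table missing columns {sorted(missing)}")
    return [
        SpeciesRecord(
            species=row.species,
            group=row.group,
            protein_coding_genes=int(row.protein_coding_genes),
            p3a_count=int(row.p3a_count),
        )
        for row in frame.itertuples()
    ]


def _summary(values: list[float]) -> GroupSummary:
    n = len(values)
    if n == 0:
        raise ValueError("empty group")
    mean = sum(values) / n
    if n < 2:
        return GroupSummary(n=n, mean=mean, sd=None, sem=None)
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    sd = math.sqrt(var)
    return GroupSummary(n=n, mean=mean, sd=sd, sem=sd / math.sqrt(n))


def group_summary(
    records: list[SpeciesRecord], field: str = "p3a_count"
) -> dict[str, GroupSummary]:
    """Per-group n/mean/SD/SEM of a field (p3a_count, ratio or
    protein_coding_genes).  Groups with a single record get mean only
    (SD and SEM are None)."""
    if field not in ("p3a_count", "ratio", "protein_coding_genes"):
        raise ValueError(f"unknown field {field!r}")
    groups: dict[str, list[float]] = {}
    for rec in records:
        groups.setdefault(rec.group, []).append(float(getattr(rec, field)))
    return {name: _summary(vals) for name, vals in sorted(groups.items())}


def two_sample_t(group_a: list[float], group_b: list[float]) -> GroupComparison:
    """Pooled-variance two-sided Student's t-test."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 values")
    a, b = _summary(list(group_a)), _summary(list(group_b))
    df = a.n + b.n - 2
    pooled = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if pooled == 0:
        if a.mean == b.mean:
            return GroupComparison(a, b, t=0.0, df=df, p=1.0)
        raise DegenerateVarianceError(
            "zero pooled variance with unequal means: t is undefined"
        )
    t = (a.mean - b.mean) / math.sqrt(pooled * (1 / a.n + 1 / b.n))
    p = 2 * t_dist.sf(abs(t), df)
    return GroupComparison(a, b, t=t, df=df, p=float(p))


def compare_groups(
    records: list[SpeciesRecord], field: str = "p3a_count"
) -> GroupComparison:
    """Glycophyte-vs-halophyte comparison on one field of a species table."""
    values = {GLYCOPHYTE: [], HALOPHYTE: []}
    for rec in records:
        if rec.group in values:
            values[rec.group].append(float(getattr(rec, field)))
    return two_sample_t(values[GLYCOPHYTE], values[HALOPHYTE])
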