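"""Cohort construction: region/hemisphere/sex grouping and age matching.

Channels are grouped by (region, hemisphere); within a group the two
sexes are compared only when each contributes at least five *distinct
patients* (channels never count twice for the same patient).  Groups
failing the threshold are retained but flagged ineligible and excluded
from downstream statistics.

Age matching selects k patients per sex minimizing

    |mean_F - mean_M| + lambda * (sd_F + sd_M),      lambda = 0.1,

by exhaustive enumeration of all per-sex k-subsets (seeded random search
when a sex has more than 25 patients, where C(n, k) becomes impractical).
The mean-difference term dominates; the sd term breaks near-ties toward
tighter age distributions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import METADATA_COLUMNS

__all__ = [
    "RegionGroup",
    "AgeSummary",
    "build_groups",
    "age_summary",
    "age_matched_subsample",
    "MIN_PATIENTS_PER_SEX",
]

MIN_PATIENTS_PER_SEX = 5

# age-matching objective weight on the sd term
_LAMBDA = 0.1

# exhaustive subset search above this per-sex patient count is impractical
_EXHAUSTIVE_LIMIT = 25


@dataclass(frozen=True)
class RegionGroup:
    """All channels of one (region, hemisphere), split by sex.

    ``female`` / ``male`` map patient_id -> list of channel_ids; ``ages``
    maps patient_id -> age in years.  ``eligible`` is True iff both sexes
    have at least ``min_patients`` distinct patients.
    """

    region: str
    hemisphere: str
    female: dict = field(default_factory=dict)
    male: dict = field(default_factory=dict)
    ages: dict = field(default_factory=dict)
    min_patients: int = MIN_PATIENTS_PER_SEX

    @property
    def eligible(self) -> bool:
        return (
            len(self.female) >= self.min_patients
            and len(self.male) >= self.min_patients
        )

    def patients(self, sex: str) -> dict:
        if sex == "F":
            return self.female
        if sex == "M":
            return self.male
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")

    def channel_ids(self, sex: str) -> list[str]:
        return [ch for chans in self.patients(sex).values() for ch in chans]


@dataclass(frozen=True)
class AgeSummary:
    """Per-sex age statistics over distinct patients."""

    sex: str
    n: int
    mean_years: float
    sd_years: float
    degenerate: bool = False  # single patient: sd undefined, reported as 0


def _require_columns(metadata: pd.DataFrame) -> None:
    required = [c for c in METADATA_COLUMNS if c != "fs_hz"]
    missing = [c for c in required if c not in metadata.columns]
    if missing:
        raise KeyError(f"metadata is missing required columns: {missing}")


def build_groups(
    metadata: pd.DataFrame, min_patients: int = MIN_PATIENTS_PER_SEX
) -> list[RegionGroup]:
    """One RegionGroup per (region, hemisphere) present in the metadata.

    Eligibility counts distinct patients, not channels.  Region labels are
    matched verbatim.  Raises ``KeyError`` on missing columns and
    ``ValueError`` on sexes outside {F, M}.
    """
    _require_columns(metadata)
    bad_sex = set(metadata["sex"].unique()) - {"F", "M"}
    if bad_sex:
        raise ValueError(
            f"sex column must contain only 'F'/'M'; found {sorted(bad_sex)} "
            f"(normalize with pipeline.read_metadata)"
        )
    groups = []
    for (region, hemisphere), sub in metadata.groupby(
        ["region", "hemisphere"], sort=True
    ):
        female: dict[str, list[str]] = {}
        male: dict[str, list[str]] = {}
        ages: dict[str, float] = {}
        for row in sub.itertuples(index=False):
            target = female if row.sex == "F" else male
            target.setdefault(row.patient_id, []).append(row.channel_id)
            ages.setdefault(row.patient_id, float(row.age))
        groups.append(
            RegionGroup(
                region=str(region),
                hemisphere=str(hemisphere),
                female=female,
                male=male,
                ages=ages,
                min_patients=min_patients,
            )
        )
    return groups


def age_summary(group: RegionGroup) -> dict[str, AgeSummary]:
    """Mean and sample sd (ddof=1) of distinct patients' ages, per sex."""
    out = {}
    for sex in ("F", "M"):
        ids = sorted(group.patients(sex))
        ages = np.array([group.ages[p] for p in ids], dtype=float)
        n = len(ages)
        if n == 0:
            out[sex] = AgeSummary(sex=sex, n=0, mean_years=float("nan"),
                                  sd_years=0.0, degenerate=True)
        elif n == 1:
            out[sex] = AgeSummary(sex=sex, n=1, mean_years=float(ages[0]),
                                  sd_years=0.0, degenerate=True)
        else:
            out[sex] = AgeSummary(
                sex=sex,
                n=n,
                mean_years=float(ages.mean()),
                sd_years=float(ages.std(ddof=1)),
            )
    return out


def _objective(ages_f: np.ndarray, ages_m: np.ndarray) -> float:
    sd_f = ages_f.std(ddof=1) if len(ages_f) > 1 else 0.0
    sd_m = ages_m.std(ddof=1) if len(ages_m) > 1 else 0.0
    return abs(ages_f.mean() - ages_m.mean()) + _LAMBDA * (sd_f + sd_m)


def _subset_iter(
    ids: list[str], k: int, rng: np.random.Generator, n_draws: int
):
    if len(ids) <= _EXHAUSTIVE_LIMIT:
        yield from itertools.combinations(ids, k)
    else:
        for _ in range(n_draws):
            yield tuple(sorted(rng.choice(ids, size=k, replace=False)))


def age_matched_subsample(
    group: RegionGroup, k: int = 5, seed: int = 0, n_draws: int = 10_000
) -> RegionGroup:
    """k patients per sex minimizing the age-matching objective.

    Enumerates every (F-subset, M-subset) pair when both sexes have at
    most 25 patients; otherwise draws ``n_draws`` seeded random subsets
    for the oversized sex.  Ties are broken toward the lexicographically
    smallest (F ids, M ids) pair, so the result is deterministic.

    Raises ``ValueError`` when either sex has fewer than k patients.
    """
    ids_f = sorted(group.female)
    ids_m = sorted(group.male)
    if len(ids_f) < k or len(ids_m) < k:
        raise ValueError(
            f"age matching needs >= {k} patients per sex; group "
            f"{group.region}/{group.hemisphere} has {len(ids_f)} F, {len(ids_m)} M"
        )
    rng = np.random.default_rng(seed)
    subsets_f = list(_subset_iter(ids_f, k, rng, n_draws))
    subsets_m = list(_subset_iter(ids_m, k, rng, n_draws))

    def _stats(subsets):
        ages = np.array([[group.ages[p] for p in s] for s in subsets])
        sds = ages.std(axis=1, ddof=1) if k > 1 else np.zeros(len(subsets))
        return ages.mean(axis=1), sds

    means_f, sds_f = _stats(subsets_f)
    means_m, sds_m = _stats(subsets_m)
    best: tuple[float, tuple, tuple] | None = None
    for i, sub_f in enumerate(subsets_f):
        obj = np.abs(means_f[i] - means_m) + _LAMBDA * (sds_f[i] + sds_m)
        j = int(np.argmin(obj))  # first minimum = lexicographically smallest M subset
        key = (float(obj[j]), sub_f, subsets_m[j])
        if best is None or key < best:
            best = key
    _, sub_f, sub_m = best
    return replace(
        group,
        female={p: group.female[p] for p in sub_f},
        male={p: group.male[p] for p in sub_m},
        ages={p: group.ages[p] for p in (*sub_f, *sub_m)},
    )
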