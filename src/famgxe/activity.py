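"""Activity-diary energy expenditure.

A 3-day diary records the dominant activity for each 15-minute period of
the day (96 periods/day) as a category code 1-9 of increasing intensity.
Total daily energy expenditure (TDEE, kcal/day) is

    TDEE = weight_kg * sum_c n_c * cost_c / 3

where n_c counts 15-min periods of category c over the 3 days and cost_c
is the per-category median energy cost in kcal/kg/15 min.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_PERIODS_PER_DAY = 96
N_DAYS = 3
N_CATEGORIES = 9

#: Default per-category energy costs, kcal/kg/15 min. These are external
#: constants from the Bouchard 3-day activity-record literature (approximate
#: median cost of each category), supplied as a configurable default; they
#: are not study-specific estimates.
BOUCHARD_COSTS = (0.26, 0.38, 0.57, 0.69, 0.84, 1.2, 1.4, 1.5, 2.0)


@dataclass(frozen=True)
class EnergyCostTable:
    """Energy cost of each diary category, kcal/kg/15 min, strictly increasing."""

    cost: tuple[float, ...] = BOUCHARD_COSTS

    def __post_init__(self) -> None:
        c = np.asarray(self.cost, dtype=float)
        if c.shape != (N_CATEGORIES,):
            raise ValueError(f"energy cost table must have {N_CATEGORIES} entries")
        if not np.all(c > 0):
            raise ValueError("energy costs must be positive")
        if not np.all(np.diff(c) > 0):
            raise ValueError("energy costs must be strictly increasing in category")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.cost, dtype=float)


@dataclass(frozen=True)
class DiaryRecord:
    """3 days x 96 quarter-hour category codes (1-9) for one individual."""

    individual_id: str
    days: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if len(self.days) != N_DAYS:
            raise ValueError(
                f"diary for {self.individual_id!r} must have {N_DAYS} days, "
                f"got {len(self.days)}"
            )
        for d, day in enumerate(self.days, start=1):
            if len(day) != N_PERIODS_PER_DAY:
                raise ValueError(
                    f"diary for {self.individual_id!r} day {d} has "
                    f"{len(day)} periods, expected {N_PERIODS_PER_DAY}"
                )
            for code in day:
                if not 1 <= int(code) <= N_CATEGORIES:
                    raise ValueError(
                        f"diary for {self.individual_id!r} day {d} has "
                        f"category code {code} outside 1..{N_CATEGORIES}"
                    )

    def category_counts(self) -> np.ndarray:
        """Number of 15-min periods per category over all 3 days (length 9)."""
        flat = np.concatenate([np.asarray(d, dtype=int) for d in self.days])
        return np.bincount(flat, minlength=N_CATEGORIES + 1)[1:]


@dataclass(frozen=True)
class EnergyExpenditure:
    individual_id: str
    tdee: float  # kcal/day

    def __post_init__(self) -> None:
        if not self.tdee > 0:
            raise ValueError("TDEE must be positive")


def tdee_from_diary(
    diary: DiaryRecord,
    weight: float,
    costs: EnergyCostTable | None = None,
) -> EnergyExpenditure:
    """TDEE in kcal/day from a 3-day diary and body weight in kg.

    Category counts are summed over the 3 days, weighted by the per-category
    cost, multiplied by body weight and divided by 3.  The result depends
    only on category counts, not period ordering.
    """
    if not weight > 0:
        raise ValueError(f"weight must be positive, got {weight}")
    costs = costs or EnergyCostTable()
    n_c = diary.category_counts()
    tdee = float(weight * n_c @ costs.as_array() / N_DAYS)
    return EnergyExpenditure(individual_id=diary.individual_id, tdee=tdee)


@dataclass(frozen=True)
class TdeeStandardization:
    """Sample mean/SD transform between kcal/day and the standardized scale."""

    mean: float
    sd: float

    def forward(self, tdee) -> np.ndarray:
        return (np.asarray(tdee, dtype=float) - self.mean) / self.sd

    def inverse(self, z) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sd + self.mean


def standardize_tdee(
    values: Sequence[EnergyExpenditure] | Sequence[float] | np.ndarray,
) -> tuple[np.ndarray, TdeeStandardization]:
    """Z-score TDEE values (sample SD, denominator n-1).

    Returns the standardized vector together with the (mean, SD) transform so
    interaction parameters can be reported on both the standardized and the
    kcal/day scales.  Constant input is rejected: a constant environment
    leaves the interaction model unidentifiable.
    """
    arr = np.asarray(
        [v.tdee if isinstance(v, EnergyExpenditure) else float(v) for v in values],
        dtype=float,
    )
    if arr.size < 2:
        raise ValueError("need at least 2 TDEE values to standardize")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        raise ValueError("constant TDEE: interaction model unidentifiable")
    tf = TdeeStandardization(mean=mean, sd=sd)
    return tf.forward(arr), tf


def read_diaries(path: str | Path) -> list[DiaryRecord]:
    """Read a diary CSV with columns individual_id, day (1-3), p1..p96."""
    df = pd.read_csv(path)
    pcols = [f"p{k}" for k in range(1, N_PERIODS_PER_DAY + 1)]
    missing = set(["individual_id", "day", *pcols]) - set(df.columns)
    if missing:
        raise ValueError(f"diary file missing columns: {sorted(missing)[:5]}")
    records = []
    for iid, grp in df.groupby("individual_id", sort=False):
        grp = grp.sort_values("day")
        if list(grp["day"]) != [1, 2, 3]:
            raise ValueError(f"diary for {iid!r} must have days 1,2,3")
        days = tuple(tuple(int(v) for v in row) for row in grp[pcols].to_numpy())
        records.append(DiaryRecord(individual_id=str(iid), days=days))
    return records


def write_diaries(records: Iterable[DiaryRecord], path: str | Path) -> None:
    pcols = [f"p{k}" for k in range(1, N_PERIODS_PER_DAY + 1)]
    rows = []
    for rec in records:
        for d, day in enumerate(rec.days, start=1):
            rows.append([rec.individual_id, d, *day])
    pd.DataFrame(rows, columns=["individual_id", "day", *pcols]).to_csv(
        path, index=False
    )
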