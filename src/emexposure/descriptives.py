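"""Descriptive surfaces: test-combination ascertainment and the
outcome x exposure x gender cross-tabulation with binomial rates.

Rates are reported as percentages with a binomial standard error
``100 * sqrt(p(1-p)/n)`` on the percentage scale. Rounding follows the
half-up convention of printed tables: two decimals for cross-tab rates,
integer percent for ascertainment rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .cohort import (
    NEGATIVE,
    PH_COLUMNS,
    PH_THRESHOLDS,
    POSITIVE,
    UNKNOWN,
    CohortTable,
)

TEST_LABELS = {"scalp_ph": "scalp", "arterial_ph": "arterial", "venous_ph": "venous"}


@dataclass(frozen=True)
class RateCell:
    """A count, a denominator, and the binomial percentage rate with SE."""

    cases: int
    total: int
    pct: float
    se_pct: float

    @classmethod
    def undefined(cls) -> "RateCell":
        return cls(cases=0, total=0, pct=float("nan"), se_pct=float("nan"))


def rate_and_se(cases: int, total: int) -> RateCell:
    """Percentage rate and its binomial standard error.

    A zero denominator yields NaN rate and SE (undefined, not zero).
    """
    if total < 0 or cases < 0:
        raise ValueError("counts must be nonnegative")
    if cases > total:
        raise ValueError(f"cases ({cases}) exceed total ({total})")
    if total == 0:
        return RateCell.undefined()
    p = cases / total
    return RateCell(
        cases=int(cases),
        total=int(total),
        pct=100.0 * p,
        se_pct=100.0 * float(np.sqrt(p * (1.0 - p) / total)),
    )


@dataclass(frozen=True)
class AscertainmentRow:
    """Counts for one combination of pH tests performed."""

    test_combination: frozenset[str]
    n_subjects: int
    n_all_positive: int
    n_any_positive: int

    def __post_init__(self) -> None:
        assert self.n_all_positive <= self.n_any_positive <= self.n_subjects

    @property
    def pct_all(self) -> float:
        return round_half_up(100.0 * self.n_all_positive / self.n_subjects) if self.n_subjects else float("nan")

    @property
    def pct_any(self) -> float:
        return round_half_up(100.0 * self.n_any_positive / self.n_subjects) if self.n_subjects else float("nan")


def _combination_order() -> list[frozenset[str]]:
    """Three tests first, then pairs, then singles, in panel column order."""
    labels = [TEST_LABELS[c] for c in PH_COLUMNS]
    order: list[frozenset[str]] = [frozenset(labels)]
    order += [frozenset(c) for c in combinations(labels, 2)]
    order += [frozenset([l]) for l in labels]
    return order


def ascertainment_table(table: CohortTable) -> list[AscertainmentRow]:
    """Per-test-combination counts of subjects, all-positive and any-positive.

    Returns one row per non-empty combination observed in the data, ordered
    from all-three to single tests, plus a final any-of-the-three totals row
    aggregating every tested subject.
    """
    df = table.df
    present = {}
    positive = {}
    n = len(df)
    for col, threshold in PH_THRESHOLDS.items():
        if col in df.columns:
            present[col] = df[col].notna().to_numpy()
            positive[col] = present[col] & (df[col].to_numpy(float) < threshold)
        else:
            present[col] = np.zeros(n, dtype=bool)
            positive[col] = np.zeros(n, dtype=bool)

    any_present = np.zeros(n, dtype=bool)
    any_pos = np.zeros(n, dtype=bool)
    all_pos = np.ones(n, dtype=bool)
    for col in PH_COLUMNS:
        any_present |= present[col]
        any_pos |= positive[col]
        all_pos &= ~present[col] | positive[col]
    all_pos &= any_present

    rows: list[AscertainmentRow] = []
    for combo in _combination_order():
        mask = any_present.copy()
        for col, label in TEST_LABELS.items():
            mask &= present[col] == (label in combo)
        if not mask.any():
            continue
        rows.append(
            AscertainmentRow(
                test_combination=combo,
                n_subjects=int(mask.sum()),
                n_all_positive=int((mask & all_pos).sum()),
                n_any_positive=int((mask & any_pos).sum()),
            )
        )
    total = AscertainmentRow(
        test_combination=frozenset({"any"}),
        n_subjects=int(sum(r.n_subjects for r in rows)),
        n_all_positive=int(sum(r.n_all_positive for r in rows)),
        n_any_positive=int(sum(r.n_any_positive for r in rows)),
    )
    rows.append(total)
    return rows


def ascertainment_frame(rows: list[AscertainmentRow]) -> pd.DataFrame:
    """Ascertainment rows as a tidy DataFrame."""
    return pd.DataFrame(
        {
            "tests": ["+".join(sorted(r.test_combination)) for r in rows],
            "n_subjects": [r.n_subjects for r in rows],
            "n_all_positive": [r.n_all_positive for r in rows],
            "pct_all": [r.pct_all for r in rows],
            "n_any_positive": [r.n_any_positive for r in rows],
            "pct_any": [r.pct_any for r in rows],
        }
    )


EXPOSURE_COLUMNS = (POSITIVE, NEGATIVE, UNKNOWN, "total")


def asd_by_exposure_crosstab(
    table: CohortTable, stratify_by_gender: bool = True
) -> dict[str, dict[str, RateCell]]:
    """Outcome counts and rates by exposure status, optionally per gender.

    Returns a grid ``{stratum: {exposure_state: RateCell}}`` where stratum
    is ``both`` plus (when stratified) ``male`` and ``female``, and each
    row carries a ``total`` column summing the three exposure states.
    """
    df = table.df.copy()
    df["_exposure"] = table.exposure_status()
    strata = {"both": df}
    if stratify_by_gender:
        strata["male"] = df[df["gender"] == "male"]
        strata["female"] = df[df["gender"] == "female"]

    grid: dict[str, dict[str, RateCell]] = {}
    for name, sub in strata.items():
        row: dict[str, RateCell] = {}
        for state in (POSITIVE, NEGATIVE, UNKNOWN):
            cell = sub[sub["_exposure"] == state]
            row[state] = rate_and_se(int(cell["asd"].sum()), len(cell))
        row["total"] = rate_and_se(int(sub["asd"].sum()), len(sub))
        grid[name] = row
    return grid


def crosstab_frame(grid: dict[str, dict[str, RateCell]]) -> pd.DataFrame:
    """Cross-tab grid as a long DataFrame with half-up 2-dp rounded rates."""
    records = []
    for stratum, row in grid.items():
        for state in EXPOSURE_COLUMNS:
            cell = row[state]
            records.append(
                {
                    "gender": stratum,
                    "hypoxia": state,
                    "cases": cell.cases,
                    "total": cell.total,
                    "pct": round_half_up(cell.pct, 2) if np.isfinite(cell.pct) else float("nan"),
                    "se_pct": round_half_up(cell.se_pct, 2) if np.isfinite(cell.se_pct) else float("nan"),
                }
            )
    return pd.DataFrame(records)
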