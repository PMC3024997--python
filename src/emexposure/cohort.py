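"""Cohort data model: records, schema, CSV I/O, design encoding and the
blood-pH exposure classifier.

A cohort is one row per child: a binary outcome (``asd``), a tri-state
exposure (``hypoxia``: positive / negative / unknown) that may instead be
derived from up to three blood-pH measurements, categorical maternal and
obstetric covariates (the Z of the exposure model), confounders such as
birth year and socio-economic class (the W of the outcome model), gender
and an optional full-term flag. Simulated cohorts additionally carry the
true exposure and the missingness indicator so recovery experiments can
score estimates against the truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"
TRISTATE = (POSITIVE, NEGATIVE, UNKNOWN)

#: Diagnostic thresholds: a test is positive iff strictly below its cut-off.
PH_THRESHOLDS: dict[str, float] = {
    "scalp_ph": 7.25,
    "arterial_ph": 7.20,
    "venous_ph": 7.28,
}
PH_COLUMNS = tuple(PH_THRESHOLDS)

RESERVED_COLUMNS = ("id", "gender", "asd", "hypoxia", "fullterm") + PH_COLUMNS
TRUTH_COLUMNS = ("truth_x", "missing_indicator")

GENDERS = ("female", "male")  # reference category first


class CohortValidationError(ValueError):
    """Raised when a cohort file or table violates its schema."""


@dataclass(frozen=True)
class PHPanel:
    """Up to three blood-pH measurements for one child.

    A fully absent panel is legal and means the child was not tested.
    """

    scalp_ph: float | None = None
    arterial_ph: float | None = None
    venous_ph: float | None = None

    def __post_init__(self) -> None:
        for name in PH_COLUMNS:
            value = getattr(self, name)
            if value is None:
                continue
            if not np.isfinite(value) or not (0.0 < value < 14.0):
                raise CohortValidationError(
                    f"{name}={value!r} is not a valid pH (must be in (0, 14))"
                )

    def present(self) -> dict[str, float]:
        return {
            name: getattr(self, name)
            for name in PH_COLUMNS
            if getattr(self, name) is not None
        }


def classify_hypoxia(panel: PHPanel, rule: str = "any_positive") -> str:
    """Classify exposure from a pH panel.

    A single test is positive iff strictly below its threshold (scalp < 7.25,
    arterial < 7.20, venous < 7.28). Under ``any_positive`` (the case
    definition) the child is positive if at least one performed test is
    positive; under ``all_positive`` only if every performed test is. A child
    with no tests is ``unknown``.
    """
    if rule not in ("any_positive", "all_positive"):
        raise ValueError(f"unknown rule {rule!r}")
    tests = panel.present()
    if not tests:
        return UNKNOWN
    flags = [value < PH_THRESHOLDS[name] for name, value in tests.items()]
    hit = any(flags) if rule == "any_positive" else all(flags)
    return POSITIVE if hit else NEGATIVE


@dataclass(frozen=True)
class CohortSchema:
    """Ordered categories for every categorical covariate.

    The first listed category of each covariate is its reference level in
    design encoding.
    """

    covariates: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, cats in self.covariates.items():
            if len(cats) < 2:
                raise CohortValidationError(f"covariate {name!r} needs >= 2 categories")
            if len(set(cats)) != len(cats):
                raise CohortValidationError(f"covariate {name!r} has duplicate categories")

    def reference(self, name: str) -> str:
        return self.covariates[name][0]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        covs = raw.get("covariates", raw) if isinstance(raw, dict) else raw
        return cls(covariates={k: [str(c) for c in v] for k, v in covs.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"covariates": self.covariates}, fh, sort_keys=False)


@dataclass
class CohortTable:
    """A cohort as a DataFrame plus the covariate schema it conforms to."""

    df: pd.DataFrame
    schema: CohortSchema

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_truth(self) -> bool:
        return all(c in self.df.columns for c in TRUTH_COLUMNS)

    def validate(self) -> None:
        df = self.df
        for col in ("id", "gender", "asd"):
            if col not in df.columns:
                raise CohortValidationError(f"required column {col!r} missing")
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].unique()[:5]
            raise CohortValidationError(f"duplicate ids: {list(dupes)}")
        bad_gender = ~df["gender"].isin(GENDERS)
        if bad_gender.any():
            raise CohortValidationError(
                f"invalid gender values in rows {list(df.index[bad_gender][:5])}"
            )
        if not df["asd"].isin([0, 1]).all():
            raise CohortValidationError("asd must be 0/1")
        if "hypoxia" in df.columns:
            bad = df["hypoxia"].notna() & ~df["hypoxia"].isin(TRISTATE)
            if bad.any():
                raise CohortValidationError(
                    f"invalid hypoxia values in rows {list(df.index[bad][:5])}"
                )
        for name, cats in self.schema.covariates.items():
            if name not in df.columns:
                continue
            observed = df[name].dropna()
            bad = ~observed.isin(cats)
            if bad.any():
                rows = list(observed.index[bad][:10])
                raise CohortValidationError(
                    f"covariate {name!r}: labels outside schema in rows {rows}"
                )
        for name in PH_COLUMNS:
            if name not in df.columns:
                continue
            vals = df[name].dropna()
            bad = ~((vals > 0.0) & (vals < 14.0))
            if bad.any():
                rows = list(vals.index[bad][:10])
                raise CohortValidationError(f"{name}: pH out of (0, 14) in rows {rows}")

    def exposure_status(self) -> pd.Series:
        """The tri-state exposure column, defaulting absent cells to unknown."""
        if "hypoxia" not in self.df.columns:
            return pd.Series(UNKNOWN, index=self.df.index, name="hypoxia")
        return self.df["hypoxia"].fillna(UNKNOWN)


def resolve_exposure(table: CohortTable, rule: str = "any_positive") -> CohortTable:
    """Fill the exposure column from the pH panel columns.

    Children without any pH measurement become ``unknown``; an existing
    ``hypoxia`` column is overwritten so the classification rule is uniform.
    """
    if rule not in ("any_positive", "all_positive"):
        raise ValueError(f"unknown rule {rule!r}")
    df = table.df.copy()
    n = len(df)
    any_present = np.zeros(n, dtype=bool)
    any_pos = np.zeros(n, dtype=bool)
    all_pos = np.ones(n, dtype=bool)
    for name, threshold in PH_THRESHOLDS.items():
        if name not in df.columns:
            continue
        present = df[name].notna().to_numpy()
        pos = present & (df[name].to_numpy(float) < threshold)
        any_present |= present
        any_pos |= pos
        all_pos &= ~present | pos
    hit = any_pos if rule == "any_positive" else (all_pos & any_present)
    status = np.where(any_present, np.where(hit, POSITIVE, NEGATIVE), UNKNOWN)
    df["hypoxia"] = status
    return CohortTable(df=df, schema=table.schema)


def read_cohort(
    path: str | Path,
    schema: CohortSchema,
    missing_codes: Sequence[str] = ("",),
) -> CohortTable:
    """Read a cohort CSV.

    Cells matching ``missing_codes`` become absent values. Numeric columns
    (asd, fullterm, pH panel, truth columns) are parsed strictly: a
    non-numeric cell raises a validation error naming the record and field.
    """
    df = pd.read_csv(
        path,
        dtype=str,
        keep_default_na=False,
        na_values=list(missing_codes),
        skipinitialspace=True,
    )
    if "id" not in df.columns:
        raise CohortValidationError("cohort file lacks an 'id' column")

    def parse_numeric(col: str, integer: bool) -> None:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & parsed.isna()
        if bad.any():
            rec = df.loc[bad, "id"].iloc[0]
            raise CohortValidationError(
                f"record {rec!r}: cannot parse {col}={df.loc[bad, col].iloc[0]!r}"
            )
        df[col] = parsed.astype("Int64") if integer else parsed

    for col in ("asd", "fullterm") + TRUTH_COLUMNS:
        if col in df.columns:
            parse_numeric(col, integer=True)
    for col in PH_COLUMNS:
        if col in df.columns:
            parse_numeric(col, integer=False)
    table = CohortTable(df=df, schema=schema)
    logger.info("read %d records from %s", len(table), path)
    return table


MISSING_TOKEN = ""  # documented CSV encoding of an absent value


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV with schema-ordered columns.

    Observable columns come first (id, gender, asd, exposure, pH panel,
    fullterm, covariates in schema order); simulation truth columns, when
    present, are appended last.
    """
    df = table.df
    front = [c for c in RESERVED_COLUMNS if c in df.columns]
    covs = [c for c in table.schema.covariates if c in df.columns]
    truth = [c for c in TRUTH_COLUMNS if c in df.columns]
    other = [c for c in df.columns if c not in front + covs + truth]
    df.to_csv(path, index=False, columns=front + other + covs + truth, na_rep=MISSING_TOKEN)


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the outcome model and the exposure model.

    ``outcome_terms`` always contains the exposure term and may add
    confounders (W), ``gender`` and the product term ``gender:<exposure>``.
    ``exposure_terms`` are the Z covariates predicting the exposure.
    """

    exposure: str = "hypoxia"
    outcome_terms: tuple[str, ...] = ("hypoxia",)
    exposure_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcome_terms", tuple(self.outcome_terms))
        object.__setattr__(self, "exposure_terms", tuple(self.exposure_terms))
        if self.outcome_terms.count(self.exposure) != 1:
            raise ValueError(
                f"exposure term {self.exposure!r} must appear exactly once in outcome_terms"
            )
        for terms in (self.outcome_terms, self.exposure_terms):
            if len(set(terms)) != len(terms):
                raise ValueError("duplicated term in model specification")

    @property
    def interaction(self) -> str | None:
        product = f"gender:{self.exposure}"
        return product if product in self.outcome_terms else None

    def with_interaction(self) -> "ModelSpec":
        terms = list(self.outcome_terms)
        if "gender" not in terms:
            terms.append("gender")
        product = f"gender:{self.exposure}"
        if product not in terms:
            terms.append(product)
        return replace(self, outcome_terms=tuple(terms))


def encode_design(
    df: pd.DataFrame,
    terms: Iterable[str],
    schema: CohortSchema,
) -> tuple[np.ndarray, list[str], pd.Index]:
    """Reference-cell design matrix for the requested terms.

    A k-category covariate contributes k-1 indicator columns named
    ``<covariate>=<category>`` (reference = first listed category);
    ``gender`` contributes ``gender=male``; a numeric 0/1 column passes
    through under its own name. The intercept column is always first.
    Rows with an absent value in any requested term are excluded (their
    count is logged) and the retained index is returned.
    """
    terms = list(terms)
    needed: list[str] = []
    for term in terms:
        if term == "gender":
            needed.append("gender")
        elif term in schema.covariates or term in df.columns:
            needed.append(term)
        else:
            raise KeyError(f"term {term!r} not in schema or table")
    keep = df.index
    if needed:
        keep = df.index[df[needed].notna().all(axis=1)]
    n_dropped = len(df) - len(keep)
    if n_dropped:
        logger.info("encode_design: excluded %d records with absent values", n_dropped)
    sub = df.loc[keep]

    columns: list[np.ndarray] = [np.ones(len(sub))]
    names: list[str] = ["intercept"]
    for term in terms:
        if term == "gender":
            columns.append((sub["gender"] == "male").to_numpy(float))
            names.append("gender=male")
        elif term in schema.covariates:
            cats = schema.covariates[term]
            for cat in cats[1:]:
                columns.append((sub[term] == cat).to_numpy(float))
                names.append(f"{term}={cat}")
        else:
            col = pd.to_numeric(sub[term])
            columns.append(col.to_numpy(float))
            names.append(term)
    return np.column_stack(columns), names, keep


def subset(table: CohortTable, predicate: str) -> CohortTable:
    """Restrict to a gender stratum or to full-term births.

    ``fullterm_only`` drops records whose gestational-age flag is absent
    and logs how many were dropped (such children stay in all-ages
    analyses).
    """
    df = table.df
    if predicate in ("gender=male", "gender=female"):
        value = predicate.split("=")[1]
        out = df[df["gender"] == value]
    elif predicate == "fullterm_only":
        if "fullterm" not in df.columns:
            raise KeyError("table has no 'fullterm' column")
        absent = int(df["fullterm"].isna().sum())
        if absent:
            logger.warning("fullterm_only: dropping %d records with absent gestational age", absent)
        out = df[df["fullterm"] == 1]
        if out.empty:
            logger.warning("fullterm_only: no full-term records remain")
    else:
        raise ValueError(f"unknown predicate {predicate!r}")
    return CohortTable(df=out.copy(), schema=table.schema)
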