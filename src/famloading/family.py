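"""Family-tree data model for interview-based family history of depression/anxiety.

A participant (proband) reports, for each first-degree relative (biological
parents and siblings), whether they ever recognised depressive/anxiety
problems in that relative.  Two aggregate endorsement criteria are recorded
per relative:

* ``endorsement_symptoms`` — at least one question on the presence of
  depressive/anxiety episodes, core symptoms, or restrictions was endorsed;
* ``endorsement_treatment`` — at least one question on receiving treatment or
  being admitted to a hospital/psychiatric ward was endorsed.

A relative counts as *affected* only when **both** criteria are met; requiring
the treatment criterion guards against the well-documented tendency of
affected probands to over-report psychopathology in their relatives.  The
dichotomous family-history indicator (FH) is positive iff at least one
first-degree relative is affected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Relation",
    "Relative",
    "Family",
    "MissingDataError",
    "SchemaError",
    "classify_relative",
    "family_history",
    "families_from_frame",
    "families_to_frame",
    "read_relatives_csv",
    "write_relatives_csv",
    "validate_relatives_frame",
    "classification_report",
]

#: maximum plausible human age; ages beyond this are treated as data errors
MAX_AGE = 120.0

RELATIVE_COLUMNS = [
    "proband_id",
    "relation",
    "age_years",
    "endorsement_symptoms",
    "endorsement_treatment",
]


class Relation(str, Enum):
    """First-degree relative type.  Offspring are not modelled: the family
    interview covers biological parents and siblings only."""

    PARENT = "parent"
    SIBLING = "sibling"


class MissingDataError(ValueError):
    """A required per-relative field (endorsement flag, age, status) is missing."""


class SchemaError(ValueError):
    """A relative-level table violates the expected column/value schema."""


def classify_relative(
    endorsement_symptoms: bool | None,
    endorsement_treatment: bool | None,
    *,
    label: str = "relative",
) -> bool:
    """Affected-status rule: both the symptom and the treatment criterion.

    Parameters
    ----------
    endorsement_symptoms
        Any episode / core-symptom / restriction question endorsed.
    endorsement_treatment
        Any treatment / hospital-admission question endorsed.
    label
        Identifier used in the error message when a flag is missing.

    Returns
    -------
    bool
        ``True`` iff both criteria are met.
    """
    for name, flag in (
        ("endorsement_symptoms", endorsement_symptoms),
        ("endorsement_treatment", endorsement_treatment),
    ):
        if flag is None or (isinstance(flag, float) and np.isnan(flag)):
            raise MissingDataError(f"{label}: missing {name} flag")
    return bool(endorsement_symptoms) and bool(endorsement_treatment)


@dataclass
class Relative:
    """One first-degree family member.

    ``age_years`` is the observation age at interview, or the age at death for
    deceased relatives (the standard censoring choice).  ``affected`` may be
    supplied directly (override) or is derived from the two endorsement flags;
    supplying both inconsistently is an error.
    """

    relation: Relation
    age_years: float
    endorsement_symptoms: bool | None = None
    endorsement_treatment: bool | None = None
    affected: bool | None = None
    label: str = "relative"

    def __post_init__(self) -> None:
        self.relation = Relation(self.relation)
        if not np.isfinite(self.age_years) or self.age_years < 0:
            raise ValueError(f"{self.label}: age_years must be a finite non-negative number")
        if self.age_years > MAX_AGE:
            raise ValueError(f"{self.label}: implausible age {self.age_years} > {MAX_AGE}")
        has_flags = (
            self.endorsement_symptoms is not None and self.endorsement_treatment is not None
        )
        if has_flags:
            derived = classify_relative(
                self.endorsement_symptoms, self.endorsement_treatment, label=self.label
            )
            if self.affected is None:
                self.affected = derived
            elif bool(self.affected) != derived:
                raise ValueError(
                    f"{self.label}: supplied affected={self.affected} contradicts the "
                    f"endorsement flags (rule gives {derived})"
                )
        elif self.affected is None:
            raise MissingDataError(
                f"{self.label}: affected status unresolved (no endorsement flags, no override)"
            )
        self.affected = bool(self.affected)


@dataclass
class Family:
    """A proband's set of first-degree relatives (possibly empty)."""

    proband_id: str
    relatives: list[Relative] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.relatives)

    @property
    def n_affected(self) -> int:
        return sum(1 for r in self.relatives if r.affected)


def family_history(family: Family) -> bool:
    """Dichotomous FH indicator: ``True`` iff >= 1 relative is affected.

    An empty family is FH- (vacuous disjunction); a warning is logged because
    an empty family usually signals missing interview data rather than a
    genuinely relative-less participant.
    """
    if family.n == 0:
        logger.warning("family %s has no relatives; FH set to negative", family.proband_id)
        return False
    for r in family.relatives:
        if r.affected is None:
            raise MissingDataError(f"{family.proband_id}/{r.label}: unresolved affected status")
    return any(r.affected for r in family.relatives)


# ---------------------------------------------------------------------------
# tabular interchange (relative-level CSV)
# ---------------------------------------------------------------------------


def _as_bool_series(s: pd.Series, column: str) -> pd.Series:
    out = pd.to_numeric(s, errors="coerce")
    bad = out.notna() & ~out.isin([0, 1])
    if bad.any():
        rows = list(out.index[bad][:5])
        raise SchemaError(f"column {column!r}: non-0/1 values at rows {rows}")
    return out


def validate_relatives_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a relative-level table.

    Required columns: proband_id, relation, age_years, endorsement_symptoms,
    endorsement_treatment.  Optional: ``affected`` (0/1 override).  Returns a
    normalised copy with a resolved boolean ``affected`` column.  Errors name
    the offending column and row numbers (0-based, data rows).
    """
    missing = [c for c in RELATIVE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"relative-level table missing required columns: {missing}")
    df = df.reset_index(drop=True).copy()

    rel = df["relation"].astype(str).str.strip().str.lower()
    valid = {r.value for r in Relation}
    bad = ~rel.isin(valid)
    if bad.any():
        raise SchemaError(
            f"column 'relation': values outside {sorted(valid)} at rows {list(df.index[bad][:5])}"
        )
    df["relation"] = rel

    age = pd.to_numeric(df["age_years"], errors="coerce")
    bad = age.isna() | (age < 0) | (age > MAX_AGE)
    if bad.any():
        raise SchemaError(
            f"column 'age_years': missing/negative/implausible at rows {list(df.index[bad][:5])}"
        )
    df["age_years"] = age.astype(float)

    sym = _as_bool_series(df["endorsement_symptoms"], "endorsement_symptoms")
    trt = _as_bool_series(df["endorsement_treatment"], "endorsement_treatment")
    derived = (sym == 1) & (trt == 1)
    flags_ok = sym.notna() & trt.notna()

    if "affected" in df.columns:
        aff = _as_bool_series(df["affected"], "affected")
        conflict = flags_ok & aff.notna() & (aff.astype(float) != derived.astype(float))
        if conflict.any():
            raise SchemaError(
                "column 'affected': override contradicts the endorsement-flag rule "
                f"at rows {list(df.index[conflict][:5])}"
            )
        resolved = aff.where(aff.notna(), derived.where(flags_ok))
    else:
        resolved = derived.where(flags_ok)

    unresolved = resolved.isna()
    if unresolved.any():
        raise MissingDataError(
            "affected status unresolved (missing endorsement flags and no override) "
            f"at rows {list(df.index[unresolved][:5])}"
        )
    df["endorsement_symptoms"] = sym.fillna(0).astype(int)
    df["endorsement_treatment"] = trt.fillna(0).astype(int)
    df["affected"] = resolved.astype(bool)
    return df


def families_from_frame(df: pd.DataFrame) -> list[Family]:
    """Build :class:`Family` objects from a (validated or raw) relative table."""
    df = validate_relatives_frame(df)
    families: list[Family] = []
    for pid, grp in df.groupby("proband_id", sort=False):
        rels = [
            Relative(
                relation=row.relation,
                age_years=row.age_years,
                endorsement_symptoms=bool(row.endorsement_symptoms),
                endorsement_treatment=bool(row.endorsement_treatment),
                label=f"{pid}[{i}]",
            )
            for i, row in enumerate(grp.itertuples())
        ]
        families.append(Family(proband_id=str(pid), relatives=rels))
    return families


def families_to_frame(families: Iterable[Family]) -> pd.DataFrame:
    rows = []
    for fam in families:
        for r in fam.relatives:
            rows.append(
                {
                    "proband_id": fam.proband_id,
                    "relation": r.relation.value,
                    "age_years": r.age_years,
                    "endorsement_symptoms": int(bool(r.endorsement_symptoms)),
                    "endorsement_treatment": int(bool(r.endorsement_treatment)),
                    "affected": int(r.affected),
                }
            )
    return pd.DataFrame(rows, columns=RELATIVE_COLUMNS + ["affected"])


def read_relatives_csv(path) -> pd.DataFrame:
    """Read and validate a relative-level CSV (UTF-8, header row, 0/1 booleans)."""
    df = pd.read_csv(path)
    return validate_relatives_frame(df)


def write_relatives_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("endorsement_symptoms", "endorsement_treatment", "affected"):
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


def classification_report(df: pd.DataFrame) -> str:
    """Human-readable log of per-relative classification decisions."""
    df = validate_relatives_frame(df)
    lines = []
    for row in df.itertuples():
        status = "AFFECTED" if row.affected else "unaffected"
        lines.append(
            f"{row.proband_id}: {row.relation} age {row.age_years:g} "
            f"sym={int(row.endorsement_symptoms)} trt={int(row.endorsement_treatment)} -> {status}"
        )
    return "\n".join(lines)
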