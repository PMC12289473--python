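"""Cohort phenotype frequencies, recurrent-variant counts, ACMG combining.

Covers the descriptive-statistics side of a rare-disease cohort study: per
feature frequencies over patients with a recorded +/- status (patients marked
``n.a.`` are excluded from the denominator, and the printed percentage is the
floor of 100*numerator/denominator), distinct-carrier counts of a recurrent
variant, and the standard ACMG/AMP pathogenic-side evidence combining rules
(Pathogenic / Likely pathogenic / VUS).
"""

from __future__ import annotations

import dataclasses
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FeatureCount",
    "VariantRecord",
    "feature_frequency",
    "complementary_percents",
    "summarize_cohort",
    "count_variant_carriers",
    "acmg_classify",
    "ACMG_CODES",
    "load_per_patient_table",
    "load_feature_counts",
    "load_variant_table",
]

_PLUS, _MINUS, _NA = "+", "-", "n.a."


class ParseError(ValueError):
    """A clinical table cell or field could not be interpreted."""


@dataclasses.dataclass(frozen=True)
class FeatureCount:
    """A phenotype feature's cohort frequency.

    ``percent`` is ``floor(100 * numerator / denominator)``, or ``None`` when
    no patient has a recorded status (denominator 0, not computable).
    """

    feature: str
    numerator: int
    denominator: int
    n_na: int
    percent: int | None


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One patient-variant row of a cohort variant table."""

    patient_id: str
    cdna: str
    protein: str
    zygosity: str  # "het" or "hom"
    criteria: tuple[str, ...]
    classification: str


def feature_frequency(numerator: int, denominator: int) -> int:
    """Integer percent by the floor rule used in cohort tables (5/12 -> 41)."""
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if not 0 <= numerator <= denominator:
        raise ValueError(f"numerator {numerator} outside [0, {denominator}]")
    return (100 * numerator) // denominator


def complementary_percents(n_first: int, n_second: int) -> tuple[int, int]:
    """Two-class split printed as complementary percents (e.g. 5F/7M -> 41/59).

    The first class gets the floor percent; the second the complement to 100,
    so the pair always sums to 100 as printed.
    """
    first = feature_frequency(n_first, n_first + n_second)
    return first, 100 - first


def summarize_cohort(table: pd.DataFrame) -> list[FeatureCount]:
    """Per-feature counts from a patients x features table of ``+ / - / n.a.``.

    Rows are patients, columns features.  Unknown cell symbols raise a
    :class:`ParseError` naming the offending row and column.
    """
    out: list[FeatureCount] = []
    for feature in table.columns:
        num = den = na = 0
        for patient, cell in table[feature].items():
            cell = str(cell).strip()
            if cell == _PLUS:
                num += 1
                den += 1
            elif cell == _MINUS:
                den += 1
            elif cell == _NA:
                na += 1
            else:
                raise ParseError(
                    f"unknown symbol {cell!r} at patient {patient!r}, feature {feature!r}"
                )
        percent = feature_frequency(num, den) if den > 0 else None
        out.append(
            FeatureCount(
                feature=str(feature), numerator=num, denominator=den, n_na=na, percent=percent
            )
        )
    return out


_CDNA_RE = re.compile(r"^c\.[0-9*+-][0-9_+*>A-Za-z-]*$")


def count_variant_carriers(records: Iterable[VariantRecord], cdna: str) -> int:
    """Distinct patients carrying a variant (homozygotes count once)."""
    if not _CDNA_RE.match(cdna):
        raise ParseError(f"malformed cDNA string {cdna!r}")
    return len({r.patient_id for r in records if r.cdna == cdna})


# ---------------------------------------------------------------------------
# ACMG pathogenic-side evidence combining
# ---------------------------------------------------------------------------

ACMG_CODES = frozenset(
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
)


def acmg_classify(criteria: Sequence[str]) -> str:
    """Combine pathogenic-side ACMG evidence codes into a classification.

    Duplicate codes are collapsed; benign-side codes are out of scope and
    rejected as unknown.  Returns ``"Pathogenic"``, ``"Likely pathogenic"``
    or ``"VUS"`` per the standard combining algorithm.
    """
    codes = set(criteria)
    unknown = codes - ACMG_CODES
    if unknown:
        raise ValueError(f"unknown ACMG codes: {sorted(unknown)}")
    vs = "PVS1" in codes
    ps = sum(1 for c in codes if c.startswith("PS"))
    pm = sum(1 for c in codes if c.startswith("PM"))
    pp = sum(1 for c in codes if c.startswith("PP"))

    pathogenic = (
        (vs and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    if pathogenic:
        return "Pathogenic"
    likely = (
        (vs and pm >= 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    if likely:
        return "Likely pathogenic"
    return "VUS"


# ---------------------------------------------------------------------------
# bundled fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str, path: str | Path | None) -> Path:
    if path is not None:
        return Path(path)
    return Path(str(resources.files("gestaltcohort.data").joinpath(name)))


def load_per_patient_table(path: str | Path | None = None) -> pd.DataFrame:
    """Patients x features ``+ / - / n.a.`` table.

    The bundled default is a synthetic reconstruction consistent with the
    published aggregate counts (only the two index patients' columns are
    published per patient).
    """
    p = _data_path("per_patient_phenotypes_synthetic.tsv", path)
    return pd.read_csv(p, sep="\t", index_col="patient_id", dtype=str, comment="#")


def load_feature_counts(path: str | Path | None = None) -> pd.DataFrame:
    """Published aggregate counts: feature, numerator, denominator, n_na, percent."""
    p = _data_path("table_phenotype_counts.tsv", path)
    return pd.read_csv(p, sep="\t", comment="#")


def load_variant_table(path: str | Path | None = None) -> list[VariantRecord]:
    """Cohort variant table as :class:`VariantRecord` rows.

    Criteria are ``+``-separated ACMG codes; ``classification`` is the
    classification printed in the source table (which for two rows does not
    follow the standard combining algorithm — see docs/methods.md).
    """
    p = _data_path("table_variants.tsv", path)
    df = pd.read_csv(p, sep="\t", dtype=str, comment="#")
    records = []
    for row in df.itertuples(index=False):
        if row.zygosity not in ("het", "hom"):
            raise ParseError(f"unknown zygosity {row.zygosity!r} for {row.patient_id}")
        records.append(
            VariantRecord(
                patient_id=row.patient_id,
                cdna=row.cdna,
                protein=row.protein,
                zygosity=row.zygosity,
                criteria=tuple(row.criteria.split("+")),
                classification=row.classification,
            )
        )
    return records
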