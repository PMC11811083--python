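"""Cohort table handling: Engel-outcome normalization, inclusion filtering
and the demographic summary used to validate a cohort file.

The cohort file is a CSV with one row per reviewed patient and columns
``id, sex, age, exclusion, procedure, lobe, side, etiology, engel``.  A blank
``exclusion`` cell means the patient is included in the study; codes 1-4
record why a patient was excluded (1 = no localizing seizure activity,
2 = failed sEEG leads, 3 = grid/strip monitoring instead of sEEG,
4 = bilateral diffuse onset).  The Engel surgical-outcome column accepts
sub-classed roman variants ("Ia", "I-D"), plain romans and arabic numerals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "normalize_engel",
    "read_cohort",
    "load_reference_cohort",
    "filter_cohort",
    "cohort_summary",
]

ENGEL_CLASSES = ("I", "II", "III", "IV")

_ENGEL_NUMERAL = {"1": "I", "2": "II", "3": "III", "4": "IV"}
# Longest-first so "III" is not consumed as "II"+"I".
_ENGEL_ROMAN = ("IV", "III", "II", "I")


def normalize_engel(engel_raw: str) -> str:
    """Map a raw Engel outcome string to its top-level class I-IV.

    Accepts sub-classed variants ("Ia", "I-D"), case differences and arabic
    numerals ("1" -> "I").  Raises ``ValueError`` on anything else.
    """
    if not isinstance(engel_raw, str) or not engel_raw.strip():
        raise ValueError("empty Engel outcome string")
    s = engel_raw.strip().upper()
    if s in _ENGEL_NUMERAL:
        return _ENGEL_NUMERAL[s]
    for roman in _ENGEL_ROMAN:
        # top-level class followed only by a sub-class suffix (letter,
        # optionally separated by - or space), e.g. "Ia", "I-D", "IVB"
        if re.fullmatch(rf"{roman}(?:[-\s]?[A-Z])?", s):
            return roman
    raise ValueError(
        f"unrecognized Engel outcome {engel_raw!r}; accepted forms are "
        "roman classes I-IV with an optional sub-class letter (e.g. 'Ia', "
        "'I-D') or arabic numerals 1-4"
    )


@dataclass
class PatientRecord:
    """One reviewed patient of the surgical cohort.

    ``sex`` is 0 = male, 1 = female; ``procedure`` 1 = laser ablation,
    2 = open craniotomy, 3 = responsive neurostimulation; ``lobe`` 1 = frontal,
    2 = temporal, 3 = parietal, 4 = occipital, 5 = two or more lobes; ``side``
    0 = left, 1 = right, 2 = bilateral.  ``exclusion`` is ``None`` for
    included patients.
    """

    id: str
    sex: int | None
    age: float | None
    exclusion: int | None
    procedure: int | None
    lobe: int | None
    side: int | None
    etiology: int | None
    engel_raw: str
    engel_class: str | None

    @property
    def included(self) -> bool:
        return self.exclusion is None


def _opt_int(v) -> int | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return int(float(v))


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Parse a cohort CSV into :class:`PatientRecord` rows."""
    df = pd.read_csv(path, dtype={"engel": str, "id": str})
    required = {"id", "sex", "age", "exclusion", "engel"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        raw = row["engel"]
        raw = "" if (not isinstance(raw, str)) else raw.strip()
        records.append(
            PatientRecord(
                id=str(row["id"]),
                sex=_opt_int(row.get("sex")),
                age=None if pd.isna(row.get("age")) else float(row["age"]),
                exclusion=_opt_int(row.get("exclusion")),
                procedure=_opt_int(row.get("procedure")),
                lobe=_opt_int(row.get("lobe")),
                side=_opt_int(row.get("side")),
                etiology=_opt_int(row.get("etiology")),
                engel_raw=raw,
                engel_class=normalize_engel(raw) if raw else None,
            )
        )
    return records


def load_reference_cohort() -> list[PatientRecord]:
    """Load the packaged 30-patient pediatric surgical-review cohort table."""
    with resources.as_file(
        resources.files("imdnm").joinpath("datasets/cohort_reference.csv")
    ) as p:
        return read_cohort(p)


def filter_cohort(
    records: list[PatientRecord],
) -> tuple[list[PatientRecord], dict[int, int]]:
    """Partition records into the included set and per-code exclusion counts."""
    included = [r for r in records if r.included]
    excluded: dict[int, int] = {}
    for r in records:
        if not r.included:
            excluded[r.exclusion] = excluded.get(r.exclusion, 0) + 1
    return included, excluded


def cohort_summary(included: list[PatientRecord]) -> dict:
    """Exact demographic and outcome counts for an included cohort.

    Every included record must carry an Engel class.  Mean age is rounded to
    one decimal.
    """
    for r in included:
        if r.engel_class is None:
            raise ValueError(f"included patient {r.id!r} has no Engel outcome")
    ages = [r.age for r in included if r.age is not None]
    return {
        "n": len(included),
        "n_female": sum(1 for r in included if r.sex == 1),
        "age_mean": round(float(np.mean(ages)), 1) if ages else float("nan"),
        "age_range": (min(ages), max(ages)) if ages else (None, None),
        "engel": {
            c: sum(1 for r in included if r.engel_class == c)
            for c in ENGEL_CLASSES
        },
        "procedure": {
            p: sum(1 for r in included if r.procedure == p) for p in (1, 2, 3)
        },
        "side": {s: sum(1 for r in included if r.side == s) for s in (0, 1, 2)},
        "lobe": {l: sum(1 for r in included if r.lobe == l) for l in (1, 2, 3, 4, 5)},
    }
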