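"""Study-level evidence tables, IPD tables and scale conversions.

Treatment effects are handled throughout on the log hazard-ratio scale,
where normality of the estimates is a reasonable approximation.  Published
results are usually reported as a hazard ratio with a 95% confidence
interval; :func:`hr_ci_to_log` converts them, and :func:`log_to_hr_ci`
round-trips back.

Exchange formats are plain CSV:

* study table: ``study_id, ref, comp, loghr_os, se_os, loghr_pfs, se_pfs``
  with missing estimates as empty cells;
* IPD table: ``study_id, arm, time_months, event`` (event 1, censored 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: two-sided 97.5% standard-normal quantile, kept at full precision so that
#: CI -> SE -> CI round-trips are tight.
Z975 = 1.959964

STUDY_COLUMNS = ["study_id", "ref", "comp", "loghr_os", "se_os", "loghr_pfs", "se_pfs"]
IPD_COLUMNS = ["study_id", "arm", "time_months", "event"]


class ValidationError(ValueError):
    """Raised when an input table or record violates its contract."""


@dataclass(frozen=True)
class StudyRecord:
    """One trial's treatment contrast on OS and/or PFS (log HR scale).

    ``y_*`` is the log hazard ratio of ``comparator_treatment`` versus
    ``reference_treatment``; ``se_*`` its standard error.  Either outcome may
    be absent (``None``), but not both, and an SE is present iff its
    estimate is.
    """

    study_id: str
    reference_treatment: str
    comparator_treatment: str
    y_os: float | None = None
    se_os: float | None = None
    y_pfs: float | None = None
    se_pfs: float | None = None

    def __post_init__(self) -> None:
        if self.y_os is None and self.y_pfs is None:
            raise ValidationError(
                f"study {self.study_id!r}: both outcomes absent; at least one of "
                "(y_os, y_pfs) must be present"
            )
        for name, y, se in (("os", self.y_os, self.se_os), ("pfs", self.y_pfs, self.se_pfs)):
            if (y is None) != (se is None):
                raise ValidationError(
                    f"study {self.study_id!r}: y_{name} and se_{name} must be "
                    "present or absent together"
                )
            if y is not None:
                if not (math.isfinite(y) and math.isfinite(se)):
                    raise ValidationError(
                        f"study {self.study_id!r}: non-finite estimate for {name}"
                    )
                if se <= 0:
                    raise ValidationError(
                        f"study {self.study_id!r}: se_{name} must be > 0, got {se}"
                    )

    @property
    def has_os(self) -> bool:
        return self.y_os is not None

    @property
    def has_pfs(self) -> bool:
        return self.y_pfs is not None


@dataclass(frozen=True)
class TreatmentSet:
    """Declared set of treatment codes with display names and a baseline."""

    codes: tuple[str, ...]
    baseline: str
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise ValidationError("treatment codes must be unique")
        if self.baseline not in self.codes:
            raise ValidationError(
                f"baseline {self.baseline!r} is not a member of {self.codes}"
            )

    def display(self, code: str) -> str:
        return self.names.get(code, code)

    def validate_records(self, studies: list[StudyRecord]) -> None:
        declared = set(self.codes)
        for s in studies:
            for code in (s.reference_treatment, s.comparator_treatment):
                if code not in declared:
                    raise ValidationError(
                        f"study {s.study_id!r} uses undeclared treatment {code!r}"
                    )


def hr_ci_to_log(hr: float, lower: float, upper: float) -> tuple[float, float]:
    """Convert a hazard ratio with 95% CI to (log HR, SE).

    ``se = (ln upper - ln lower) / (2 * 1.959964)``, the usual normal
    approximation on the log scale.
    """
    if min(hr, lower, upper) <= 0:
        raise ValueError(f"hazard ratios must be positive, got ({hr}, {lower}, {upper})")
    if not (lower <= hr <= upper):
        raise ValueError(f"require lower <= hr <= upper, got ({lower}, {hr}, {upper})")
    y = math.log(hr)
    se = (math.log(upper) - math.log(lower)) / (2.0 * Z975)
    return y, se


def log_to_hr_ci(y: float, se: float) -> tuple[float, float, float]:
    """Inverse of :func:`hr_ci_to_log` for a symmetric log-scale interval."""
    if se <= 0:
        raise ValueError("se must be > 0")
    return math.exp(y), math.exp(y - Z975 * se), math.exp(y + Z975 * se)


def _cell(raw, row: int, col: str) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    if isinstance(raw, str) and raw.strip() == "":
        return None
    try:
        return float(raw)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"row {row}, column {col!r}: malformed numeric cell {raw!r}") from exc


def read_study_table(path) -> list[StudyRecord]:
    """Read a study-table CSV into validated :class:`StudyRecord` objects.

    Empty cells denote absent estimates (never sentinel numbers).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"study table {path}: missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        records.append(
            StudyRecord(
                study_id=row["study_id"],
                reference_treatment=row["ref"],
                comparator_treatment=row["comp"],
                y_os=_cell(row["loghr_os"], i, "loghr_os"),
                se_os=_cell(row["se_os"], i, "se_os"),
                y_pfs=_cell(row["loghr_pfs"], i, "loghr_pfs"),
                se_pfs=_cell(row["se_pfs"], i, "se_pfs"),
            )
        )
    return records


def write_study_table(records: list[StudyRecord], path) -> None:
    rows = [
        {
            "study_id": r.study_id,
            "ref": r.reference_treatment,
            "comp": r.comparator_treatment,
            "loghr_os": r.y_os,
            "se_os": r.se_os,
            "loghr_pfs": r.y_pfs,
            "se_pfs": r.se_pfs,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=STUDY_COLUMNS).to_csv(path, index=False)


def read_ipd(path) -> pd.DataFrame:
    """Read an IPD CSV (``study_id, arm, time_months, event``) and validate."""
    df = pd.read_csv(path)
    missing = [c for c in IPD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"IPD table {path}: missing columns {missing}")
    return validate_ipd(df)


def validate_ipd(df: pd.DataFrame) -> pd.DataFrame:
    t = np.asarray(df["time_months"], dtype=float)
    e = np.asarray(df["event"], dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValidationError("IPD: time_months must be finite and >= 0")
    if not np.all(np.isin(e, (0.0, 1.0))):
        raise ValidationError("IPD: event must be 0 (censored) or 1 (event)")
    return df


def write_ipd(df: pd.DataFrame, path) -> None:
    df.loc[:, IPD_COLUMNS].to_csv(path, index=False)
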