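"""Reconstruction of right-censored time-to-event records from survey reports.

Household surveys record FGM twice over: each woman aged 15-49 reports her own
status and age at cutting (self report), and reports status, current age and
age at cutting for each of her daughters aged 0-14 (proxy report).  This
module re-orders those wide survey rows into one event-history record per
person:

* a cut person with a valid event age ``a`` becomes ``(time=a, event=True)``;
* an uncut person is right-censored at her current age,
  ``(time=current_age, event=False)``;
* cut persons whose event age is unknown, missing, or later than their current
  age are excluded and counted in an :class:`ExclusionLog` — no imputation.

"During infancy" replies are mapped to age 0 and flagged so sensitivity
re-runs can drop them.  Birth year is ``interview_year - current_age``;
records born before 1960 are excluded, matching the earliest cohort the
analysis uses.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .km import MAX_AGE

EARLIEST_BIRTH_YEAR = 1960
#: column order of a normalized event table
EVENT_COLUMNS = (
    "time", "event", "weight", "birth_year", "cohort", "residence",
    "country", "survey_id", "stratum_id", "psu_id", "source", "infancy_flag",
)


class ConfigError(ValueError):
    """A mapping config is missing something the pipeline needs."""


# ---------------------------------------------------------------------------
# age-at-event parsing

@dataclass(frozen=True)
class ParsedAge:
    """Outcome of parsing a raw age-at-FGM value.

    ``kind`` is one of ``"age"`` (with ``value`` set), ``"infancy"``,
    ``"unknown"`` or ``"missing"``.
    """

    kind: str
    value: int | None = None


@dataclass(frozen=True)
class AgeCodes:
    """Survey-specific string codes for the special age-at-event categories."""

    infancy: frozenset = frozenset({"during infancy", "95"})
    unknown: frozenset = frozenset({"don't know", "dont know", "dk", "98"})
    missing: frozenset = frozenset({"", "nan", "na", "99"})


DEFAULT_CODES = AgeCodes()


def parse_age_at_fgm(raw: Any, codes: AgeCodes = DEFAULT_CODES) -> ParsedAge:
    """Classify a raw age-at-FGM cell.

    Numeric values (or numeric strings) in 0..49 parse as ages; declared
    infancy / don't-know codes map to their categories; empty cells are
    missing.  A numeric value outside [0, 49] raises, carrying the value.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return ParsedAge("missing")
    if isinstance(raw, (int, np.integer)) or (isinstance(raw, float) and raw == int(raw)):
        return _numeric_age(int(raw))
    text = str(raw).strip().lower()
    if text in codes.infancy:
        return ParsedAge("infancy")
    if text in codes.unknown:
        return ParsedAge("unknown")
    if text in codes.missing:
        return ParsedAge("missing")
    try:
        num = float(text)
    except ValueError:
        raise ValueError(f"unrecognized age-at-FGM value: {raw!r}") from None
    if num != int(num):
        raise ValueError(f"age-at-FGM must be a whole year of age, got {raw!r}")
    return _numeric_age(int(num))


def _numeric_age(age: int) -> ParsedAge:
    if not 0 <= age <= MAX_AGE:
        raise ValueError(f"age-at-FGM {age} outside [0, {MAX_AGE}]")
    return ParsedAge("age", age)


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CohortScheme:
    """Birth cohorts of width 1, 5 or 10 years anchored at 1960.

    Years from ``open_start`` (2010) onward fall in the open terminal class
    labelled "After 2009"; the widths divide 2010 - 1960 evenly so classes
    partition all birth years >= 1960.
    """

    width: int = 10
    anchor: int = EARLIEST_BIRTH_YEAR
    open_start: int = 2010
    open_label: str = "After 2009"

    def __post_init__(self):
        if self.width not in (1, 5, 10):
            raise ValueError(f"cohort width must be 1, 5 or 10, got {self.width}")

    def label(self, birth_year: int) -> str:
        if birth_year < self.anchor:
            raise ValueError(f"birth year {birth_year} precedes the {self.anchor} anchor")
        if birth_year >= self.open_start:
            return self.open_label
        start = self.anchor + self.width * ((birth_year - self.anchor) // self.width)
        if self.width == 1:
            return str(start)
        return f"{start}–{start + self.width - 1}"

    def labels(self) -> list[str]:
        """All class labels in chronological order."""
        starts = range(self.anchor, self.open_start, self.width)
        closed = [self.label(s) for s in starts]
        return closed + [self.open_label]


def assign_cohort(birth_year: int, scheme: CohortScheme) -> str:
    """Cohort label for a birth year (>= 1960)."""
    return scheme.label(birth_year)


# ---------------------------------------------------------------------------
# record conversion

@dataclass(frozen=True)
class EventRecord:
    """One person's reconstructed time-to-event datum."""

    time: int
    event: bool
    weight: float
    birth_year: int
    cohort: str
    residence: str = "unknown"
    country: str = ""
    survey_id: str = ""
    stratum_id: str = ""
    psu_id: str = ""
    source: str = "self"
    infancy_flag: bool = False

    def __post_init__(self):
        if not 0 <= self.time <= MAX_AGE:
            raise ValueError(f"time {self.time} outside [0, {MAX_AGE}]")
        if self.source == "proxy" and self.time > 14:
            raise ValueError("proxy-reported daughters are censored at 14 at most")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")


@dataclass(frozen=True)
class Excluded:
    """Sentinel returned instead of a record, carrying the exclusion reason."""

    reason: str


class ExclusionLog:
    """Per-survey counters of every record dropped, by reason.

    Supports the conservation check: input rows = retained records + total
    exclusions, per survey and overall.
    """

    def __init__(self):
        self.counts: dict[str, Counter] = {}

    def add(self, survey_id: str, reason: str, n: int = 1) -> None:
        self.counts.setdefault(survey_id, Counter())[reason] += n

    def total(self, survey_id: str | None = None) -> int:
        if survey_id is not None:
            return sum(self.counts.get(survey_id, Counter()).values())
        return sum(sum(c.values()) for c in self.counts.values())

    def merge(self, other: "ExclusionLog") -> "ExclusionLog":
        for sid, counter in other.counts.items():
            for reason, n in counter.items():
                self.add(sid, reason, n)
        return self

    def as_dict(self) -> dict:
        return {sid: dict(sorted(c.items())) for sid, c in sorted(self.counts.items())}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def __repr__(self):
        return f"ExclusionLog(total={self.total()}, surveys={len(self.counts)})"


@dataclass(frozen=True)
class RecordMeta:
    """Design and grouping labels shared by a batch of records."""

    weight: float = 1.0
    birth_year: int = EARLIEST_BIRTH_YEAR
    residence: str = "unknown"
    country: str = ""
    survey_id: str = ""
    stratum_id: str = ""
    psu_id: str = ""


def _resolve_event_age(parsed: ParsedAge | Any, codes: AgeCodes):
    if not isinstance(parsed, ParsedAge):
        parsed = parse_age_at_fgm(parsed, codes)
    return parsed


def mother_to_record(status: bool, age_at_fgm, current_age: int, meta: RecordMeta,
                     scheme: CohortScheme, codes: AgeCodes = DEFAULT_CODES,
                     ) -> EventRecord | Excluded:
    """Convert one woman's self report into an event record (or an exclusion).

    A cut woman with a valid event age ``a <= current_age`` yields
    ``(time=a, event=True)``; an uncut woman is censored at her current age.
    """
    if not 15 <= current_age <= MAX_AGE:
        return Excluded("ineligible_current_age")
    return _to_record(status, age_at_fgm, current_age, meta, scheme, codes, source="self")


def daughter_to_record(status: bool, age_at_fgm, current_age: int, mother_meta: RecordMeta,
                       scheme: CohortScheme, codes: AgeCodes = DEFAULT_CODES,
                       ) -> EventRecord | Excluded:
    """Convert one proxy-reported daughter (aged 0-14); weight is her mother's."""
    if not 0 <= current_age <= 14:
        return Excluded("ineligible_current_age")
    return _to_record(status, age_at_fgm, current_age, mother_meta, scheme, codes, source="proxy")


def _to_record(status, age_at_fgm, current_age, meta, scheme, codes, *, source):
    if meta.birth_year < scheme.anchor:
        return Excluded("birth_year_before_1960")
    cohort = scheme.label(meta.birth_year)
    infancy = False
    if status:
        parsed = _resolve_event_age(age_at_fgm, codes)
        if parsed.kind == "infancy":
            time, infancy = 0, True
        elif parsed.kind == "age":
            time = parsed.value
        elif parsed.kind == "unknown":
            return Excluded("unknown_event_age")
        else:
            return Excluded("missing_event_age")
        if time > current_age:
            return Excluded("event_age_exceeds_current_age")
        event = True
    else:
        time, event = current_age, False
    return EventRecord(
        time=time, event=event, weight=meta.weight, birth_year=meta.birth_year,
        cohort=cohort, residence=meta.residence, country=meta.country,
        survey_id=meta.survey_id, stratum_id=meta.stratum_id, psu_id=meta.psu_id,
        source=source, infancy_flag=infancy,
    )


# ---------------------------------------------------------------------------
# table-level construction

@dataclass
class ColumnMapping:
    """Names of the input columns and the codes used for statuses and ages.

    Defaults match the synthetic generator's output; a YAML/JSON config can
    override any entry for other layouts.
    """

    status: str = "fgm_status"
    age_at_fgm: str = "age_at_fgm"
    current_age: str = "current_age"
    weight: str = "weight"
    stratum: str = "stratum"
    psu: str = "cluster"
    residence: str = "residence"
    region: str = "region"
    interview_year: str = "interview_year"
    cut_codes: tuple = (1, "1", "yes", True)
    codes: AgeCodes = field(default_factory=AgeCodes)

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnMapping":
        d = dict(d)
        if "codes" in d:
            c = d["codes"]
            d["codes"] = AgeCodes(
                infancy=frozenset(str(x).lower() for x in c.get("infancy", DEFAULT_CODES.infancy)),
                unknown=frozenset(str(x).lower() for x in c.get("unknown", DEFAULT_CODES.unknown)),
                missing=frozenset(str(x).lower() for x in c.get("missing", DEFAULT_CODES.missing)),
            )
        if "cut_codes" in d:
            d["cut_codes"] = tuple(d["cut_codes"])
        return cls(**d)

    def require(self, df: pd.DataFrame, names: Iterable[str], table: str) -> None:
        missing = [getattr(self, n) for n in names if getattr(self, n) not in df.columns]
        if missing:
            raise ConfigError(f"{table} table is missing mapped column(s): {missing}")


def _is_cut(value, mapping: ColumnMapping) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {str(c).lower() for c in mapping.cut_codes}
    return value in mapping.cut_codes or value == 1


def build_event_table(women: pd.DataFrame, daughters: pd.DataFrame | None,
                      mapping: ColumnMapping | None = None,
                      scheme: CohortScheme | None = None,
                      *, survey_id: str = "", country: str = "",
                      ) -> tuple[pd.DataFrame, ExclusionLog]:
    """Build the normalized event table for one survey.

    Women contribute self reports; daughters (optional table) contribute proxy
    reports inheriting the mother's weight, which the input table must already
    carry (the synthetic generator and DHS-style extracts both do).  Returns
    the event table (columns :data:`EVENT_COLUMNS`) and the exclusion log;
    rows in = rows out + exclusions.
    """
    mapping = mapping or ColumnMapping()
    scheme = scheme or CohortScheme()
    log = ExclusionLog()
    records: list[EventRecord] = []

    def convert(df: pd.DataFrame, convert_one, table_name: str):
        if df is None or not len(df):
            return
        mapping.require(df, ("status", "age_at_fgm", "current_age", "weight",
                             "stratum", "psu", "interview_year"), table_name)
        has_residence = mapping.residence in df.columns
        cols = df.to_dict("list")
        n = len(df)
        sid_col = cols.get("survey_id", [survey_id] * n)
        res_col = cols[mapping.residence] if has_residence else ["unknown"] * n
        for i in range(n):
            cur = int(cols[mapping.current_age][i])
            meta = RecordMeta(
                weight=float(cols[mapping.weight][i]),
                birth_year=int(cols[mapping.interview_year][i]) - cur,
                residence=str(res_col[i]),
                country=country,
                survey_id=str(sid_col[i]) or survey_id,
                stratum_id=str(cols[mapping.stratum][i]),
                psu_id=str(cols[mapping.psu][i]),
            )
            out = convert_one(
                _is_cut(cols[mapping.status][i], mapping),
                cols[mapping.age_at_fgm][i], cur, meta, scheme, mapping.codes,
            )
            if isinstance(out, Excluded):
                log.add(meta.survey_id or survey_id or "?", out.reason)
            else:
                records.append(out)

    convert(women, mother_to_record, "women")
    convert(daughters, daughter_to_record, "daughters")

    table = pd.DataFrame([r.__dict__ for r in records], columns=list(EVENT_COLUMNS))
    if not len(table):
        table = table.astype({"time": np.int64, "event": bool, "weight": float,
                              "birth_year": np.int64, "infancy_flag": bool}, errors="ignore")
    return table, log
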