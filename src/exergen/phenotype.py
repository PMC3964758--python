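"""Weekly MET-hour exercise phenotype from raw activity reports.

The score for one survey is the sum over *regular leisure* exercise
activities of MET value x sessions/week x hours/session, truncated at 120
MET hours/week. Regular leisure activities are those practiced at least 3
months a year and for at least half a year, excluding transportation,
gardening, house cleaning, and compulsory physical education.

Longitudinal surveys are merged to one score per individual: scores at age
> 50 are discarded, injured-at-survey waves are dropped, and the most recent
adult (>= 18) record wins, falling back to the most recent adolescent
(13-17) and then child (< 13) record.

MET values come from age-appropriate compendia: a youth table for under-18s
and an adult table from 18 on. A small curated lookup covering common sports
ships with the package and can be replaced by any CSV with columns
``activity, youth_met, adult_met``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

TRUNCATION_CAP = 120.0
ADULT_AGE = 18.0
ADOLESCENT_AGE = 13.0
MAX_AGE = 50.0

_STRATUM_PRIORITY = {"adult": 2, "adolescent": 1, "child": 0}


class ValidationError(ValueError):
    """Malformed activity or phenotype records."""


class METLookupError(KeyError):
    """Activity absent from the MET lookup table (no silent default)."""


@dataclass
class ActivityRecord:
    individual_id: str
    survey_wave: str
    age_at_survey: float
    activity_name: str
    met_value: Optional[float]
    years_participated: float
    months_per_year: float
    times_per_week: float
    minutes_per_session: float
    leisure_flag: bool = True
    injured_at_survey: bool = False

    def __post_init__(self) -> None:
        if self.met_value is not None and self.met_value < 1.0:
            raise ValidationError(
                f"{self.individual_id}/{self.activity_name}: MET value below resting (1.0)"
            )
        if not 0.0 <= self.months_per_year <= 12.0:
            raise ValidationError(
                f"{self.individual_id}/{self.activity_name}: months_per_year outside [0, 12]"
            )
        for name in ("years_participated", "times_per_week", "minutes_per_session"):
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"{self.individual_id}/{self.activity_name}: negative {name}"
                )


@dataclass
class WaveScore:
    """One survey-wave MET-hour score, before longitudinal merging."""

    individual_id: str
    survey_wave: str
    age_at_survey: float
    weekly_met_hours: float
    injured_at_survey: bool = False


@dataclass
class PhenotypeRecord:
    individual_id: str
    weekly_met_hours: float
    source_stratum: str  # "adult" | "adolescent" | "child"
    source_wave: str


def stratum_for_age(age: float) -> str:
    if age >= ADULT_AGE:
        return "adult"
    if age >= ADOLESCENT_AGE:
        return "adolescent"
    return "child"


# ----------------------------------------------------------------------
# MET lookup
# ----------------------------------------------------------------------

def load_met_table(path: Optional[str | Path] = None) -> pd.DataFrame:
    """Load a MET lookup table (default: the curated table shipped here)."""
    if path is None:
        source = importlib.resources.files("exergen.data").joinpath("met_table.csv")
        with importlib.resources.as_file(source) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    required = {"activity", "youth_met", "adult_met"}
    if not required <= set(table.columns):
        raise ValidationError(f"MET table must have columns {sorted(required)}")
    return table.set_index("activity")


def met_lookup(activity_name: str, age: float,
               table: Optional[pd.DataFrame] = None) -> float:
    """MET value for an activity: youth table under 18, adult table from 18."""
    if table is None:
        table = load_met_table()
    if activity_name not in table.index:
        raise METLookupError(
            f"activity {activity_name!r} not in the MET lookup table"
        )
    column = "youth_met" if age < ADULT_AGE else "adult_met"
    return float(table.loc[activity_name, column])


# ----------------------------------------------------------------------
# Scoring
# ----------------------------------------------------------------------

def filter_regular_leisure(records: Iterable[ActivityRecord]) -> list[ActivityRecord]:
    """Keep leisure activities practiced >= 3 months/year for >= half a year."""
    return [
        r for r in records
        if r.leisure_flag and r.months_per_year >= 3.0 and r.years_participated >= 0.5
    ]


def met_hours(records: Iterable[ActivityRecord],
              cap: float = TRUNCATION_CAP) -> float:
    """Weekly MET hours: sum of MET x times/week x hours/session, capped.

    Records are assumed already filtered to regular leisure activities; each
    must carry a resolved ``met_value``.
    """
    if cap <= 0:
        raise ValidationError("cap must be positive")
    total = 0.0
    for r in records:
        if r.met_value is None:
            raise ValidationError(
                f"{r.individual_id}/{r.activity_name}: met_value unresolved"
            )
        total += r.met_value * r.times_per_week * r.minutes_per_session / 60.0
    return min(cap, total)


def _wave_sort_key(wave: str):
    try:
        return (0, float(wave), str(wave))
    except (TypeError, ValueError):
        return (1, 0.0, str(wave))


def merge_longitudinal(records: Iterable[WaveScore]) -> list[PhenotypeRecord]:
    """One phenotype per individual from longitudinal wave scores.

    Scores at age > 50 become missing; injured waves are dropped; the most
    recent adult record wins, then the most recent adolescent, then child.
    Recency is wave order, ties broken by higher age at survey, then lexical
    wave id. Individuals with nothing left are absent from the output.
    """
    records = list(records)
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.individual_id, r.survey_wave)
        if key in seen:
            raise ValidationError(f"duplicate record for individual/wave {key}")
        seen.add(key)
    best: dict[str, tuple[tuple, WaveScore]] = {}
    for r in records:
        if r.age_at_survey > MAX_AGE or r.injured_at_survey:
            continue
        stratum = stratum_for_age(r.age_at_survey)
        rank = (_STRATUM_PRIORITY[stratum], _wave_sort_key(r.survey_wave),
                r.age_at_survey, str(r.survey_wave))
        if r.individual_id not in best or rank > best[r.individual_id][0]:
            best[r.individual_id] = (rank, r)
    out = []
    for iid in sorted(best):
        r = best[iid][1]
        out.append(PhenotypeRecord(iid, r.weekly_met_hours,
                                   stratum_for_age(r.age_at_survey), r.survey_wave))
    return out


def score_activities(records: Iterable[ActivityRecord],
                     met_table: Optional[pd.DataFrame] = None,
                     cap: float = TRUNCATION_CAP) -> list[PhenotypeRecord]:
    """Full pipeline: filter, resolve MET values, score per wave, merge.

    Records without a ``met_value`` are resolved through :func:`met_lookup`
    at the age at survey.
    """
    if met_table is None:
        met_table = load_met_table()
    kept = filter_regular_leisure(list(records))
    waves: dict[tuple[str, str], list[ActivityRecord]] = {}
    meta: dict[tuple[str, str], tuple[float, bool]] = {}
    all_waves: set[tuple[str, str]] = set()
    for r in records:
        key = (r.individual_id, r.survey_wave)
        all_waves.add(key)
        prev = meta.get(key)
        if prev is not None and prev != (r.age_at_survey, r.injured_at_survey):
            raise ValidationError(f"inconsistent age/injury flags within wave {key}")
        meta[key] = (r.age_at_survey, r.injured_at_survey)
    for r in kept:
        waves.setdefault((r.individual_id, r.survey_wave), []).append(r)
    scores = []
    for key in sorted(all_waves):
        age, injured = meta[key]
        recs = []
        for r in waves.get(key, []):
            if r.met_value is None:
                r = ActivityRecord(**{**r.__dict__,
                                      "met_value": met_lookup(r.activity_name, age,
                                                              met_table)})
            recs.append(r)
        scores.append(WaveScore(key[0], key[1], age, met_hours(recs, cap), injured))
    return merge_longitudinal(scores)
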