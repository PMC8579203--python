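"""Global Impressions (GI) segment assignment and Complicating Factors (CFs).

The five ordinal GI segments encode increasing medical complexity:

1. HEALTHY — no chronic disease, no ADL difficulty, not cognitively
   impaired, not frail.
2. CHRONIC_ASYMPTOMATIC — a non-life-threatening chronic disease or
   case-level depression, with GALI "not limited".
3. CHRONIC_SYMPTOMATIC — a life-threatening chronic condition with GALI at
   most "limited, but not severely", or a non-life-threatening chronic
   disease / depression with GALI "limited" at any severity.
4. LONG_COURSE_DECLINE — frail or cognitively impaired.
5. LIMITED_RESERVE_EXACERBATION — a life-threatening chronic condition with
   GALI "severely limited".

An observation qualifying for several segments is assigned the most severe.
Rules are evaluated in three-valued (Kleene) logic so that missing inputs
yield UNASSIGNED only when they could actually change the outcome.

The four CFs are binary care-complexity markers: caregiver dependence,
absent social support, frequent inpatient/outpatient transitions, and
polypharmacy (5+ daily medications).  High medical needs = GI segment 4
or 5.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import pandas as pd

from .indicators import GALI, IndicatorProfile, SchemaError, _is_missing, profile_from_row

logger = logging.getLogger(__name__)

__all__ = [
    "GISegment",
    "CFProfile",
    "HealthState",
    "CFThresholds",
    "assign_gi",
    "assign_cfs",
    "collapse_to_health_state",
    "segment_panel",
]


class GISegment(enum.IntEnum):
    """Ordinal GI segment; UNASSIGNED (0) is incomparable filler."""

    UNASSIGNED = 0
    HEALTHY = 1
    CHRONIC_ASYMPTOMATIC = 2
    CHRONIC_SYMPTOMATIC = 3
    LONG_COURSE_DECLINE = 4
    LIMITED_RESERVE_EXACERBATION = 5


class HealthState(enum.Enum):
    """Collapsed 3-state (+censoring) space for the transition model."""

    LOW_NEEDS = "low"
    HIGH_NEEDS = "high"
    DEATH = "death"
    CENSORED = "censored"


#: GI segments that constitute high medical needs.
HIGH_NEEDS_SEGMENTS = frozenset(
    {GISegment.LONG_COURSE_DECLINE, GISegment.LIMITED_RESERVE_EXACERBATION}
)


@dataclass(frozen=True)
class CFThresholds:
    """Thresholds for the count-based CFs.

    polypharmacy: daily prescription medications >= 5.
    frequent transitions: inpatient admissions in the last 12 months >= 2
    (the survey gives no stated cutoff; 2 is the configurable default).
    """

    polypharmacy_meds: int = 5
    frequent_transitions_hospitalizations: int = 2


@dataclass
class CFProfile:
    caregiver_dependence: bool | None
    no_social_support: bool | None
    frequent_care_transitions: bool | None
    polypharmacy_5plus: bool | None
    any_cf: bool | None
    assessable: bool


# Kleene three-valued logic helpers: values are True, False or None (unknown)

def _and(*vals):
    if any(v is False for v in vals):
        return False
    if any(v is None for v in vals):
        return None
    return True


def _or(*vals):
    if any(v is True for v in vals):
        return True
    if any(v is None for v in vals):
        return None
    return False


def _not(v):
    return None if v is None else not v


def _gali_in(gali: GALI | None, levels) -> bool | None:
    return None if gali is None else gali in levels


def _rule_values(p: IndicatorProfile) -> dict[GISegment, bool | None]:
    """Three-valued truth of each qualifying condition."""
    not_limited = _gali_in(p.gali, {GALI.NOT_LIMITED})
    at_most_moderate = _gali_in(p.gali, {GALI.NOT_LIMITED, GALI.LIMITED_NOT_SEVERELY})
    any_limited = _gali_in(p.gali, {GALI.LIMITED_NOT_SEVERELY, GALI.SEVERELY_LIMITED})
    severe = _gali_in(p.gali, {GALI.SEVERELY_LIMITED})
    any_chronic = _or(p.has_lt_chronic, p.has_nlt_chronic)
    nlt_or_depressed = _or(p.has_nlt_chronic, p.depressed)

    return {
        GISegment.HEALTHY: _and(
            _not(any_chronic),
            _not(p.any_adl_difficulty),
            _not(p.cognitively_impaired),
            _not(p.frail),
        ),
        GISegment.CHRONIC_ASYMPTOMATIC: _and(nlt_or_depressed, not_limited),
        GISegment.CHRONIC_SYMPTOMATIC: _or(
            _and(p.has_lt_chronic, at_most_moderate),
            _and(nlt_or_depressed, any_limited),
        ),
        GISegment.LONG_COURSE_DECLINE: _or(p.frail, p.cognitively_impaired),
        GISegment.LIMITED_RESERVE_EXACERBATION: _and(p.has_lt_chronic, severe),
    }


def assign_gi(p: IndicatorProfile) -> tuple[GISegment, str | None]:
    """Assign the most severe qualifying GI segment.

    Returns ``(segment, reason)`` where ``reason`` is None for an assigned
    segment, or a code explaining non-assignment: ``"missing_data"`` when a
    missing input leaves the most severe qualifying segment ambiguous, or
    ``"no_rule"`` when the profile is complete but satisfies no qualifying
    condition (e.g. ADL difficulty alone, with no chronic disease and
    neither frailty nor impairment).
    """
    rules = _rule_values(p)
    candidate = GISegment.UNASSIGNED
    for seg in sorted(rules, key=int):
        if rules[seg] is True:
            candidate = seg
    if candidate is GISegment.UNASSIGNED:
        if any(v is None for v in rules.values()):
            return GISegment.UNASSIGNED, "missing_data"
        return GISegment.UNASSIGNED, "no_rule"
    # a more severe rule that cannot be resolved blocks assignment
    for seg, v in rules.items():
        if seg > candidate and v is None:
            return GISegment.UNASSIGNED, "missing_data"
    return candidate, None


def assign_cfs(
    meds_count=None,
    caregiver_dependent=None,
    social_support_absent=None,
    recent_hospitalizations=None,
    thresholds: CFThresholds = CFThresholds(),
) -> CFProfile:
    """Derive the four complicating-factor flags from raw items.

    Counts below zero are schema violations; a profile with all four items
    missing is not assessable.  ``any_cf`` is True as soon as one flag is
    True, False only when all four are observed False, and missing
    otherwise.
    """
    for name, v in (("meds_count", meds_count), ("recent_hospitalizations", recent_hospitalizations)):
        if not _is_missing(v) and v < 0:
            raise SchemaError(f"{name} must be nonnegative, got {v}")

    poly = None if _is_missing(meds_count) else bool(meds_count >= thresholds.polypharmacy_meds)
    transitions = (
        None
        if _is_missing(recent_hospitalizations)
        else bool(recent_hospitalizations >= thresholds.frequent_transitions_hospitalizations)
    )
    caregiver = None if _is_missing(caregiver_dependent) else bool(caregiver_dependent)
    social = None if _is_missing(social_support_absent) else bool(social_support_absent)

    flags = (caregiver, social, transitions, poly)
    assessable = any(f is not None for f in flags)
    any_cf = _or(*flags) if assessable else None
    return CFProfile(
        caregiver_dependence=caregiver,
        no_social_support=social,
        frequent_care_transitions=transitions,
        polypharmacy_5plus=poly,
        any_cf=any_cf,
        assessable=assessable,
    )


def collapse_to_health_state(segment: GISegment, vital_status: str = "alive") -> HealthState:
    """Collapse GI into the binary needs state used by the transition model.

    Death overrides any (stale) segment; an unassigned living observation
    is a censored contact — the person is known alive but their needs state
    is unknown.
    """
    if vital_status == "dead":
        return HealthState.DEATH
    if segment is GISegment.UNASSIGNED:
        return HealthState.CENSORED
    return (
        HealthState.HIGH_NEEDS
        if segment in HIGH_NEEDS_SEGMENTS
        else HealthState.LOW_NEEDS
    )


def segment_panel(
    indicators_df: pd.DataFrame,
    thresholds: CFThresholds = CFThresholds(),
) -> pd.DataFrame:
    """Append GI segment, CF flags and collapsed health state to an
    indicator-annotated panel.

    Adds ``gi_segment`` (int, 0 = unassigned), ``unassigned_reason``,
    ``cf_caregiver``, ``cf_no_social_support``, ``cf_transitions``,
    ``cf_polypharmacy``, ``any_cf``, ``cf_assessable`` and
    ``health_state``.
    """
    df = indicators_df.copy()
    segments, reasons = [], []
    cf_cols: dict[str, list] = {k: [] for k in
                                ("cf_caregiver", "cf_no_social_support", "cf_transitions",
                                 "cf_polypharmacy", "any_cf", "cf_assessable")}
    states = []
    for _, row in df.iterrows():
        seg, reason = assign_gi(profile_from_row(row))
        segments.append(int(seg))
        reasons.append(reason)
        cf = assign_cfs(
            meds_count=row.get("meds_count"),
            caregiver_dependent=row.get("caregiver_dependent"),
            social_support_absent=row.get("social_support_absent"),
            recent_hospitalizations=row.get("hospitalizations"),
            thresholds=thresholds,
        )
        cf_cols["cf_caregiver"].append(cf.caregiver_dependence)
        cf_cols["cf_no_social_support"].append(cf.no_social_support)
        cf_cols["cf_transitions"].append(cf.frequent_care_transitions)
        cf_cols["cf_polypharmacy"].append(cf.polypharmacy_5plus)
        cf_cols["any_cf"].append(cf.any_cf)
        cf_cols["cf_assessable"].append(cf.assessable)
        states.append(
            collapse_to_health_state(GISegment(int(seg)), row.get("vital_status", "alive")).value
        )
    df["gi_segment"] = segments
    df["unassigned_reason"] = reasons
    for k, v in cf_cols.items():
        df[k] = v
    df["health_state"] = states
    n_unassigned = sum(s == 0 for s in segments)
    logger.info(
        "segmented %d rows: %d assigned, %d unassigned",
        len(df), len(df) - n_unassigned, n_unassigned,
    )
    return df
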