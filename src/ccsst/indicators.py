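"""Clinical indicator scoring for aging-survey records.

Turns raw survey items — self-reported physician diagnoses, the EURO-D
depression inventory, five performance-based cognition tests, Fried-style
frailty criteria, the Global Activity Limitation Index (GALI) and ADL
difficulty counts — into the boolean/ordinal indicator profile that the
segmentation rules consume.

Missing data are handled by simple explicit policies rather than model-based
imputation: an indicator is missing when its required inputs are missing,
except for the EURO-D score which may be prorated from a minimum number of
observed items.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GALI",
    "CognitionReference",
    "MissingPolicy",
    "IndicatorProfile",
    "LT_CONDITIONS",
    "NLT_CONDITIONS",
    "CONDITION_VOCABULARY",
    "EARLY_ARTHRITIS_ITEMS",
    "LATE_ARTHRITIS_ITEMS",
    "score_euro_d",
    "score_cognition",
    "score_frailty",
    "classify_chronic",
    "arthritis_composite",
    "carry_forward_diagnoses",
    "build_cognition_reference",
    "compute_indicators",
]


class GALI(enum.Enum):
    """Global Activity Limitation Index, a single-item 3-level measure of
    long-standing (6+ months) activity limitation."""

    NOT_LIMITED = 0
    LIMITED_NOT_SEVERELY = 1
    SEVERELY_LIMITED = 2


#: Life-threatening chronic conditions: likely to dominate care management,
#: with serious consequences of lapsed monitoring.
LT_CONDITIONS = frozenset(
    {
        "heart_attack",
        "heart_failure",
        "stroke",
        "copd",
        "hip_fracture",
        "cancer",
    }
)

#: Non-life-threatening chronic conditions: require continuous surveillance
#: but are usually managed in primary/community care.  ``arthritis`` is the
#: composite over the wave-era arthritis family items.
NLT_CONDITIONS = frozenset(
    {
        "hypertension",
        "high_cholesterol",
        "diabetes",
        "ulcer",
        "parkinsons",
        "cataracts",
        "arthritis",
    }
)

CONDITION_VOCABULARY = LT_CONDITIONS | NLT_CONDITIONS

#: Arthritis-family diagnosis items asked in the first four survey waves.
EARLY_ARTHRITIS_ITEMS = ("osteoarthritis", "rheumatism", "osteoporosis")
#: Items asked from the fifth wave onward.
LATE_ARTHRITIS_ITEMS = ("rheumatoid_arthritis", "osteoarthritis_or_rheumatism")

#: Names of the five cognition tests, in canonical order.
COGNITION_TESTS = ("fluency", "immediate_recall", "delayed_recall", "orientation", "numeracy")


class SchemaError(ValueError):
    """Raised when an input violates the expected record schema."""


class ConfigurationError(ValueError):
    """Raised for invalid scoring configuration (e.g. nonpositive SDs)."""


@dataclass(frozen=True)
class MissingPolicy:
    """How partially missing item batteries are scored.

    euro_d_min_items
        Minimum observed EURO-D items required to compute a (prorated)
        score; below this the score is missing.
    frailty_determinate
        Score frailty from incomplete criteria whenever the outcome is
        already determined by the observed items (e.g. 3 observed positives
        imply frail no matter what the missing items hold).  When False all
        5 criteria are required.
    """

    euro_d_min_items: int = 10
    frailty_determinate: bool = True


@dataclass(frozen=True)
class CognitionReference:
    """Per-test mean and SD of the wave-1 reference sample.

    Impairment is defined relative to this reference: composite z-score
    strictly below ``-cutoff_sd``.
    """

    means: tuple[float, ...]
    sds: tuple[float, ...]
    cutoff_sd: float = 1.5
    n: int | None = None
    sd_convention: str = "sample (n-1 denominator)"

    def __post_init__(self) -> None:
        if len(self.means) != len(self.sds):
            raise ConfigurationError("means and sds must have equal length")
        if any(not (s > 0) for s in self.sds):
            raise ConfigurationError("reference standard deviations must be > 0")
        if not self.cutoff_sd > 0:
            raise ConfigurationError("cutoff_sd must be > 0")


@dataclass
class IndicatorProfile:
    """Derived clinical flags for one observation.

    ``None`` encodes missing throughout.  ``composite_cognition`` is in
    z-units against the wave-1 reference.
    """

    frail: bool | None = None
    cognitively_impaired: bool | None = None
    depressed: bool | None = None
    gali: GALI | None = None
    has_lt_chronic: bool | None = None
    has_nlt_chronic: bool | None = None
    any_adl_difficulty: bool | None = None
    composite_cognition: float | None = None
    euro_d_score: int | None = None


def _is_missing(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and math.isnan(x):
        return True
    return x is pd.NA or x is pd.NaT


def score_euro_d(
    items,
    policy: MissingPolicy = MissingPolicy(),
    cutoff: int = 3,
) -> tuple[int | None, bool | None]:
    """Score the 12-item EURO-D depression inventory.

    Parameters
    ----------
    items : sequence of 12 booleans, each possibly missing (None/NaN)
        Symptom endorsements.
    policy : MissingPolicy
        Governs how many observed items are required.
    cutoff : int
        Case-level depression is ``score > cutoff`` (default 3, the
        literature-standard case threshold).

    Returns
    -------
    (score, depressed)
        Integer score 0-12 (prorated to the 12-item metric when between
        ``policy.euro_d_min_items`` and 11 items are observed), and the
        case indicator; both None when too few items are observed.
    """
    items = list(items)
    if len(items) != 12:
        raise SchemaError(f"EURO-D requires exactly 12 items, got {len(items)}")
    observed = [bool(x) for x in items if not _is_missing(x)]
    n_obs = len(observed)
    if n_obs < policy.euro_d_min_items:
        return None, None
    raw = sum(observed)
    # prorate to the 12-item metric, rounding half away from the caseness side
    score = int(round(raw * 12 / n_obs)) if n_obs < 12 else raw
    return score, score > cutoff


def score_cognition(
    scores, ref: CognitionReference
) -> tuple[float | None, bool | None]:
    """Composite cognition z-score and impairment flag.

    The composite is the mean of per-test z-scores against ``ref``;
    impairment is a composite *strictly* below ``-ref.cutoff_sd``.
    Any missing test score makes both outputs missing.
    """
    scores = list(scores)
    if len(scores) != len(ref.means):
        raise SchemaError(
            f"expected {len(ref.means)} cognition scores, got {len(scores)}"
        )
    if any(_is_missing(s) for s in scores):
        return None, None
    z = [(s - m) / sd for s, m, sd in zip(scores, ref.means, ref.sds)]
    composite = float(np.mean(z))
    return composite, composite < -ref.cutoff_sd


def score_frailty(
    criteria, policy: MissingPolicy = MissingPolicy(), threshold: int = 3
) -> bool | None:
    """Fried-phenotype frailty: frail iff >= ``threshold`` of 5 criteria.

    The five criteria (exhaustion, weight loss, weakness, slowness, low
    activity) enter as precomputed booleans; survey-specific raw-item
    thresholds are applied upstream.  Under the determinate policy a
    partially observed battery is scored whenever the outcome cannot be
    changed by the missing items.
    """
    criteria = list(criteria)
    if len(criteria) != 5:
        raise SchemaError(f"frailty requires exactly 5 criteria, got {len(criteria)}")
    n_missing = sum(_is_missing(c) for c in criteria)
    n_true = sum(bool(c) for c in criteria if not _is_missing(c))
    if n_missing == 0:
        return n_true >= threshold
    if not policy.frailty_determinate:
        return None
    if n_true >= threshold:
        return True
    if n_true + n_missing < threshold:
        return False
    return None


def arthritis_composite(era_flags: dict, wave: int) -> bool | None:
    """Composite arthritis-family indicator.

    Waves 1-4 ask about osteoarthritis, rheumatism and osteoporosis; wave 5
    onward asks about rheumatoid arthritis and osteoarthritis-or-other-
    rheumatism.  True iff any era-appropriate item is endorsed.
    """
    expected = EARLY_ARTHRITIS_ITEMS if wave <= 4 else LATE_ARTHRITIS_ITEMS
    unknown = set(era_flags) - set(EARLY_ARTHRITIS_ITEMS) - set(LATE_ARTHRITIS_ITEMS)
    if unknown:
        raise SchemaError(f"unknown arthritis items: {sorted(unknown)}")
    present = [k for k in expected if k in era_flags]
    if not present:
        raise SchemaError(
            f"wave {wave} requires arthritis items {expected}, got {sorted(era_flags)}"
        )
    vals = [era_flags[k] for k in present]
    if any(not _is_missing(v) and bool(v) for v in vals):
        return True
    if all(_is_missing(v) for v in vals):
        return None
    return False


def classify_chronic(diagnosis_flags: dict) -> tuple[bool, bool]:
    """Split diagnosis flags into (life-threatening, non-life-threatening).

    ``diagnosis_flags`` is keyed by the canonical condition vocabulary;
    ``arthritis`` should already be the composited family indicator.
    Missing flags are treated as not endorsed (diagnoses, once reported,
    are carried forward upstream).
    """
    unknown = set(diagnosis_flags) - CONDITION_VOCABULARY
    if unknown:
        raise SchemaError(f"unknown condition keys: {sorted(unknown)}")
    def any_of(names):
        return any(
            not _is_missing(diagnosis_flags.get(c)) and bool(diagnosis_flags.get(c))
            for c in names
        )
    return any_of(LT_CONDITIONS), any_of(NLT_CONDITIONS)


def carry_forward_diagnoses(
    panel: pd.DataFrame,
    condition_columns,
    person_col: str = "person_id",
    time_col: str = "interview_time",
) -> pd.DataFrame:
    """Propagate chronic diagnoses to all later waves.

    Chronic conditions are persistent: a condition reported at any wave is
    assigned at that wave and all subsequent ones (cumulative OR within
    person).  Missing later reports therefore do not revoke a diagnosis.
    Row count and order are preserved; input must be time-sorted within
    person.
    """
    out = panel.copy()
    grouped_time = out.groupby(person_col, sort=False)[time_col]
    if not grouped_time.apply(lambda s: s.is_monotonic_increasing and s.is_unique).all():
        raise SchemaError("panel must be strictly time-sorted within person")
    for col in condition_columns:
        flag = out[col].map(lambda v: False if _is_missing(v) else bool(v))
        out[col] = flag.groupby(out[person_col], sort=False).cummax()
    return out


def build_cognition_reference(
    wave1: pd.DataFrame,
    test_columns=tuple(f"cog_{t}" for t in COGNITION_TESTS),
    cutoff_sd: float = 1.5,
) -> CognitionReference:
    """Per-test mean/SD over complete cases of the wave-1 reference sample.

    Uses the sample SD (n-1 denominator).  Degenerate (zero-variance) tests
    and reference samples of fewer than two complete cases are rejected.
    """
    complete = wave1[list(test_columns)].dropna()
    if len(complete) < 2:
        raise ConfigurationError("need >= 2 complete five-test observations")
    means = tuple(float(complete[c].mean()) for c in test_columns)
    sds = tuple(float(complete[c].std(ddof=1)) for c in test_columns)
    if any(s <= 0 for s in sds):
        bad = [c for c, s in zip(test_columns, sds) if s <= 0]
        raise ConfigurationError(f"zero-variance reference test(s): {bad}")
    return CognitionReference(means=means, sds=sds, cutoff_sd=cutoff_sd, n=len(complete))


# ---------------------------------------------------------------------------
# dataframe-level pipeline

EURO_D_COLUMNS = tuple(f"eurod_{i}" for i in range(1, 13))
FRAILTY_COLUMNS = tuple(f"frail_{i}" for i in range(1, 6))
COGNITION_COLUMNS = tuple(f"cog_{t}" for t in COGNITION_TESTS)


def compute_indicators(
    panel: pd.DataFrame,
    ref: CognitionReference | None = None,
    policy: MissingPolicy = MissingPolicy(),
    euro_d_cutoff: int = 3,
    frailty_threshold: int = 3,
    carry_forward: bool = True,
) -> pd.DataFrame:
    """Full raw-items -> indicator-columns pipeline.

    Expects the canonical column layout: ``dx_<condition>`` diagnosis
    columns (era-specific arthritis items), ``eurod_1..12``, ``cog_*``,
    ``frail_1..5``, ``gali`` (0/1/2 or missing), ``adl_count``, plus
    ``person_id``/``wave``/``interview_time``.  When ``ref`` is None it is
    built from the wave-1 rows.  Returns a copy with the appended columns
    ``eurod_score, depressed, composite_cognition, cognitively_impaired,
    frail, has_lt_chronic, has_nlt_chronic, any_adl_difficulty``.
    """
    df = panel.copy()
    n_in = len(df)

    # composite arthritis from whichever era items each wave carries
    def _arthritis(row):
        flags = {}
        for item in EARLY_ARTHRITIS_ITEMS + LATE_ARTHRITIS_ITEMS:
            col = f"dx_{item}"
            if col in row.index:
                flags[item] = row[col]
        era = EARLY_ARTHRITIS_ITEMS if row["wave"] <= 4 else LATE_ARTHRITIS_ITEMS
        flags = {k: v for k, v in flags.items() if k in era and not _is_missing(v)}
        if not flags:
            return np.nan
        return arthritis_composite(flags, int(row["wave"]))

    df["dx_arthritis"] = df.apply(_arthritis, axis=1)

    dx_cols = [f"dx_{c}" for c in sorted(CONDITION_VOCABULARY) if f"dx_{c}" in df.columns]
    if carry_forward:
        df = carry_forward_diagnoses(df, dx_cols)

    lt_cols = [f"dx_{c}" for c in sorted(LT_CONDITIONS) if f"dx_{c}" in df.columns]
    nlt_cols = [f"dx_{c}" for c in sorted(NLT_CONDITIONS) if f"dx_{c}" in df.columns]
    df["has_lt_chronic"] = df[lt_cols].fillna(False).astype(bool).any(axis=1) if lt_cols else False
    df["has_nlt_chronic"] = df[nlt_cols].fillna(False).astype(bool).any(axis=1) if nlt_cols else False

    eurod = df[list(EURO_D_COLUMNS)].apply(
        lambda row: score_euro_d(row.values, policy, euro_d_cutoff), axis=1
    )
    df["eurod_score"] = [s for s, _ in eurod]
    df["depressed"] = [d for _, d in eurod]

    if ref is None:
        ref = build_cognition_reference(df[df["wave"] == 1], COGNITION_COLUMNS)
    cog = df[list(COGNITION_COLUMNS)].apply(
        lambda row: score_cognition(row.values, ref), axis=1
    )
    df["composite_cognition"] = [c for c, _ in cog]
    df["cognitively_impaired"] = [i for _, i in cog]

    df["frail"] = df[list(FRAILTY_COLUMNS)].apply(
        lambda row: score_frailty(row.values, policy, frailty_threshold), axis=1
    )

    df["any_adl_difficulty"] = df["adl_count"].map(
        lambda v: None if _is_missing(v) else bool(v > 0)
    )

    logger.info("computed indicators for %d rows (%d diagnosis columns)", n_in, len(dx_cols))
    return df


def profile_from_row(row: pd.Series) -> IndicatorProfile:
    """Extract an :class:`IndicatorProfile` from an indicator-annotated row."""
    gali = row.get("gali")
    return IndicatorProfile(
        frail=None if _is_missing(row.get("frail")) else bool(row["frail"]),
        cognitively_impaired=(
            None if _is_missing(row.get("cognitively_impaired")) else bool(row["cognitively_impaired"])
        ),
        depressed=None if _is_missing(row.get("depressed")) else bool(row["depressed"]),
        gali=None if _is_missing(gali) else GALI(int(gali)),
        has_lt_chronic=None if _is_missing(row.get("has_lt_chronic")) else bool(row["has_lt_chronic"]),
        has_nlt_chronic=None if _is_missing(row.get("has_nlt_chronic")) else bool(row["has_nlt_chronic"]),
        any_adl_difficulty=(
            None if _is_missing(row.get("any_adl_difficulty")) else bool(row["any_adl_difficulty"])
        ),
        composite_cognition=(
            None if _is_missing(row.get("composite_cognition")) else float(row["composite_cognition"])
        ),
        euro_d_score=None if _is_missing(row.get("eurod_score")) else int(row["eurod_score"]),
    )
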