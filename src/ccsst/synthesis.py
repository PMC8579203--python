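"""Synthetic aging-survey panels with known ground truth.

Two generation levels, mirroring how the real instrument is exercised:

1. :func:`render_survey_items` writes raw survey items (diagnoses, GALI,
   EURO-D inventory, cognition test scores against a bundled reference,
   frailty criteria, medication counts, ...) that deterministically map
   back to a requested GI segment and CF profile through the indicator and
   segmentation modules — the round-trip property.

2. :func:`simulate_trajectories` draws latent LOW/HIGH/DEATH trajectories
   from a known covariate-dependent generator by exact (Gillespie) event
   simulation, observes them at biennial interview waves, records death at
   its exact event time, and censors interviews independently of state
   (the non-informative contact assumption).  The hidden truth is returned
   alongside the observed panel.

:func:`simulate_survey_panel` composes the two: latent states are rendered
as raw survey rows (high needs as Fried-frail profiles, low needs as a
persistent per-person mix of healthy / chronic styles so that diagnosis
carry-forward stays consistent), giving an end-to-end test bed for the
whole pipeline without any restricted survey data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indicators import (
    COGNITION_COLUMNS,
    EURO_D_COLUMNS,
    FRAILTY_COLUMNS,
    CognitionReference,
    CONDITION_VOCABULARY,
    EARLY_ARTHRITIS_ITEMS,
    LATE_ARTHRITIS_ITEMS,
)
from .segmentation import GISegment
from .multistate import LOW, HIGH, DEATH, TRANSITION_LABELS

__all__ = [
    "BUNDLED_COGNITION_REFERENCE",
    "SimulationConfig",
    "render_survey_items",
    "render_censored_contact",
    "simulate_trajectories",
    "simulate_survey_panel",
]

#: Reference distribution (synthetic wave-1 population) for the five
#: cognition tests: verbal fluency, immediate recall, delayed recall,
#: orientation, numeracy.
BUNDLED_COGNITION_REFERENCE = CognitionReference(
    means=(20.0, 5.0, 3.5, 3.7, 3.0),
    sds=(7.0, 1.8, 2.0, 0.7, 1.2),
    cutoff_sd=1.5,
)

_DX_COLUMNS = tuple(sorted(f"dx_{c}" for c in CONDITION_VOCABULARY if c != "arthritis")) + tuple(
    f"dx_{c}" for c in EARLY_ARTHRITIS_ITEMS + LATE_ARTHRITIS_ITEMS
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic panel.

    Defaults emulate a biennial aging-survey cohort followed over seven
    waves (12 years): moderate yearly progression/recovery intensities
    between the needs states, mortality concentrated in the high-needs
    state, a binary complicating-factor covariate doubling the hazard of
    progression, and non-informative interview censoring.
    """

    n_persons: int = 3000
    countries: dict = field(default_factory=lambda: {"A": 0.25, "B": 0.25, "C": 0.25, "D": 0.25})
    wave_times: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)
    baseline_intensities: dict = field(
        default_factory=lambda: {
            "low->high": 0.12,
            "high->low": 0.10,
            "low->death": 0.02,
            "high->death": 0.15,
        }
    )
    covariate_log_hr: dict = field(
        default_factory=lambda: {"any_cf": {"low->high": math.log(2.0)}}
    )
    cf_prevalence: float = 0.3
    initial_high_prob: float = 0.15
    censoring_prob: float = 0.05
    missing_gali_rate: float = 0.0
    #: fraction of persons whose HIGH state renders as a limited-reserve
    #: profile (life-threatening disease + severe limitation) instead of a
    #: frail profile; their LOW state renders as the matching chronic style
    high_limited_reserve_frac: float = 0.3
    age_range: tuple[float, float] = (50.0, 80.0)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.censoring_prob <= 1:
            raise ValueError("censoring_prob must be in [0, 1]")
        if not 0 <= self.cf_prevalence <= 1:
            raise ValueError("cf_prevalence must be in [0, 1]")
        if any(q < 0 for q in self.baseline_intensities.values()):
            raise ValueError("intensities must be nonnegative")
        if abs(sum(self.countries.values()) - 1.0) > 1e-9:
            raise ValueError("country mixing proportions must sum to 1")


# ---------------------------------------------------------------------------
# level 1: raw survey items for a target profile

_BENIGN = {
    "gali": 0,
    "adl_count": 0,
    "meds_count": 0,
    "caregiver_dependent": False,
    "social_support_absent": False,
    "hospitalizations": 0,
}


def _base_row(rng: np.random.Generator, wave: int) -> dict:
    row: dict = {}
    for col in _DX_COLUMNS:
        row[col] = False
    # era-inappropriate arthritis items are not asked
    era_absent = LATE_ARTHRITIS_ITEMS if wave <= 4 else EARLY_ARTHRITIS_ITEMS
    for item in era_absent:
        row[f"dx_{item}"] = np.nan
    for col in EURO_D_COLUMNS:
        row[col] = False
    ref = BUNDLED_COGNITION_REFERENCE
    for col, m, sd in zip(COGNITION_COLUMNS, ref.means, ref.sds):
        row[col] = m + float(rng.uniform(-0.3, 0.3)) * sd
    for col in FRAILTY_COLUMNS:
        row[col] = False
    row.update(_BENIGN)
    return row


def render_survey_items(
    gi_target: GISegment,
    cf_flags: dict | None = None,
    rng: np.random.Generator | int = 0,
    wave: int = 1,
) -> dict:
    """Raw survey items that segment exactly to ``gi_target`` + ``cf_flags``.

    ``cf_flags`` may set ``polypharmacy, transitions, caregiver, social``
    (all default False).  Raises for UNASSIGNED targets — use
    :func:`render_censored_contact` for uninformative contacts.
    """
    if gi_target is GISegment.UNASSIGNED:
        raise ValueError("cannot render an UNASSIGNED target; use render_censored_contact")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    row = _base_row(rng, wave)

    if gi_target is GISegment.HEALTHY:
        pass
    elif gi_target is GISegment.CHRONIC_ASYMPTOMATIC:
        row["dx_hypertension"] = True          # NLT disease, GALI not limited
    elif gi_target is GISegment.CHRONIC_SYMPTOMATIC:
        row["dx_stroke"] = True                # LT disease, GALI limited-not-severely
        row["gali"] = 1
    elif gi_target is GISegment.LONG_COURSE_DECLINE:
        for col in FRAILTY_COLUMNS[:3]:        # 3 of 5 Fried criteria -> frail
            row[col] = True
        row["gali"] = 1
    elif gi_target is GISegment.LIMITED_RESERVE_EXACERBATION:
        row["dx_stroke"] = True                # LT disease, GALI severely limited
        row["gali"] = 2

    cf = cf_flags or {}
    if cf.get("polypharmacy"):
        row["meds_count"] = int(rng.integers(5, 12))
    if cf.get("transitions"):
        row["hospitalizations"] = int(rng.integers(2, 5))
    if cf.get("caregiver"):
        row["caregiver_dependent"] = True
    if cf.get("social"):
        row["social_support_absent"] = True
    return row


def render_censored_contact(rng: np.random.Generator | int = 0, wave: int = 1) -> dict:
    """A contact confirming survival but too incomplete to segment.

    GALI, the frailty criteria and the cognition battery are all missing,
    so no qualifying condition can be resolved and segmentation returns
    UNASSIGNED (hence the CENSORED health state for a living person).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    row = _base_row(rng, wave)
    row["gali"] = np.nan
    for col in FRAILTY_COLUMNS:
        row[col] = np.nan
    for col in COGNITION_COLUMNS:
        row[col] = np.nan
    return row


# ---------------------------------------------------------------------------
# level 2: latent trajectories from a known generator

def _person_rates(cfg: SimulationConfig, z: dict) -> np.ndarray:
    """Allowed-transition intensities for one person's covariates."""
    q = np.array([cfg.baseline_intensities[l] for l in TRANSITION_LABELS])
    for cov, effects in cfg.covariate_log_hr.items():
        x = float(z.get(cov, 0.0))
        for label, loghr in effects.items():
            q[TRANSITION_LABELS.index(label)] *= math.exp(loghr * x)
    return q


def _gillespie(rng, q: np.ndarray, state0: int, horizon: float):
    """Exact CTMC path: list of (time, state) jumps, starting at (0, state0)."""
    out_rates = {
        LOW: ((HIGH, q[0]), (DEATH, q[2])),
        HIGH: ((LOW, q[1]), (DEATH, q[3])),
    }
    t, state = 0.0, state0
    path = [(0.0, state0)]
    while state != DEATH:
        rates = out_rates[state]
        total = sum(r for _, r in rates)
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= horizon:
            break
        u = rng.uniform(0, total)
        acc = 0.0
        for nxt, r in rates:
            acc += r
            if u < acc:
                state = nxt
                break
        path.append((t, state))
    return path


def _state_at(path, t: float) -> int:
    s = path[0][1]
    for tj, sj in path:
        if tj <= t:
            s = sj
        else:
            break
    return s


_STATE_NAMES = {LOW: "low", HIGH: "high", DEATH: "death"}


def simulate_trajectories(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the latent process and its panel observation.

    Returns ``(panel, truth)``.  ``panel`` has one row per person-contact
    with columns ``person_id, country, gender, age, wave, interview_time,
    any_cf, health_state, vital_status, death_time, weight``; deaths appear
    only through ``death_time`` (exact event time).  ``truth`` lists every
    latent jump as ``person_id, time, state``.  Identical seeds give
    identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    countries = list(cfg.countries)
    probs = np.array([cfg.countries[c] for c in countries], float)
    horizon = max(cfg.wave_times)
    panel_rows, truth_rows = [], []
    for pid in range(cfg.n_persons):
        country = countries[rng.choice(len(countries), p=probs)]
        gender = "F" if rng.uniform() < 0.5 else "M"
        age0 = float(rng.uniform(*cfg.age_range))
        any_cf = int(rng.uniform() < cfg.cf_prevalence)
        state0 = HIGH if rng.uniform() < cfg.initial_high_prob else LOW
        q = _person_rates(cfg, {"any_cf": any_cf, "gender": gender})
        path = _gillespie(rng, q, state0, horizon)
        for t, s in path:
            truth_rows.append({"person_id": pid, "time": t, "state": _STATE_NAMES[s]})
        death_time = next((t for t, s in path if s == DEATH), None)
        for w, t in enumerate(cfg.wave_times, start=1):
            if death_time is not None and t >= death_time:
                break
            censored = w > 1 and rng.uniform() < cfg.censoring_prob
            state = "censored" if censored else _STATE_NAMES[_state_at(path, t)]
            panel_rows.append({
                "person_id": pid, "country": country, "gender": gender,
                "age": age0 + t, "wave": w, "interview_time": t,
                "any_cf": any_cf, "health_state": state,
                "vital_status": "alive", "weight": 1.0,
                "death_time": death_time if death_time is not None else np.nan,
            })
    panel = pd.DataFrame(panel_rows)
    truth = pd.DataFrame(truth_rows)
    return panel, truth


# ---------------------------------------------------------------------------
# end to end: latent states rendered as raw survey rows

#: Persistent per-person rendering style for the LOW state: (segment,
#: sampling weight).  Styles keep diagnosis carry-forward consistent.
_LOW_STYLES = (
    (GISegment.HEALTHY, 0.5),
    (GISegment.CHRONIC_ASYMPTOMATIC, 0.25),
    (GISegment.CHRONIC_SYMPTOMATIC, 0.25),
)


def simulate_survey_panel(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent trajectories rendered as raw survey item rows.

    LOW needs renders as the person's persistent style (healthy or a
    chronic profile); HIGH needs renders as a Fried-frail profile on top of
    that style, making the GI -> needs-state collapse exact.  Persons with
    the complicating-factor covariate render with polypharmacy.  GALI is
    additionally dropped at ``cfg.missing_gali_rate`` to emulate item
    nonresponse.  Returns ``(survey_panel, truth)``.
    """
    panel, truth = simulate_trajectories(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    style_names = [s for s, _ in _LOW_STYLES]
    style_w = np.array([w for _, w in _LOW_STYLES])
    style_w = style_w / style_w.sum()
    styles, high_styles = {}, {}
    for pid in panel["person_id"].unique():
        if rng.uniform() < cfg.high_limited_reserve_frac:
            # limited-reserve rendering needs a persistent LT diagnosis
            styles[pid] = GISegment.CHRONIC_SYMPTOMATIC
            high_styles[pid] = GISegment.LIMITED_RESERVE_EXACERBATION
        else:
            styles[pid] = style_names[rng.choice(len(style_names), p=style_w)]
            high_styles[pid] = GISegment.LONG_COURSE_DECLINE
    rows = []
    for _, rec in panel.iterrows():
        pid = rec["person_id"]
        wave = int(rec["wave"])
        if rec["health_state"] == "censored":
            row = render_censored_contact(rng, wave)
            # CF items are still reported at uninformative contacts
            if rec["any_cf"]:
                row["meds_count"] = int(rng.integers(5, 12))
        else:
            low_style = styles[pid]
            if rec["health_state"] == "high":
                target = high_styles[pid]
            else:
                target = low_style
            row = render_survey_items(
                target,
                {"polypharmacy": bool(rec["any_cf"])},
                rng,
                wave,
            )
            # persistent chronic styles carry their diagnosis at every wave
            if low_style is GISegment.CHRONIC_ASYMPTOMATIC:
                row["dx_hypertension"] = True
            elif low_style is GISegment.CHRONIC_SYMPTOMATIC:
                row["dx_stroke"] = True
                if rec["health_state"] == "low" and target is GISegment.CHRONIC_SYMPTOMATIC:
                    row["gali"] = 1
            if rec["health_state"] == "low" and rng.uniform() < cfg.missing_gali_rate:
                row["gali"] = np.nan
        for col in ("person_id", "country", "gender", "age", "wave",
                    "interview_time", "any_cf", "vital_status", "death_time", "weight"):
            row[col] = rec[col]
        rows.append(row)
    return pd.DataFrame(rows), truth
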