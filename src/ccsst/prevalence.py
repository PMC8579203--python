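"""Survey-weighted GI x CF prevalence and cross-country high-needs ranking.

Proportions use calibrated cross-sectional weights (or 1.0 when absent) and
are renormalized over segmented observations: rows without an assigned GI
segment are excluded from denominators, with the exclusion count logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .segmentation import GISegment, HIGH_NEEDS_SEGMENTS

logger = logging.getLogger(__name__)

__all__ = ["weighted_prevalence", "high_needs_shares", "rank_countries", "plot_prevalence"]

HIGH_NEEDS_INTS = frozenset(int(s) for s in HIGH_NEEDS_SEGMENTS)


def _prepare(segmented: pd.DataFrame, weight_col: str) -> pd.DataFrame:
    df = segmented.copy()
    if weight_col not in df.columns:
        df[weight_col] = 1.0
    df[weight_col] = df[weight_col].fillna(1.0)
    if (df[weight_col] < 0).any():
        raise ValueError("weights must be nonnegative")
    n_unassigned = int((df["gi_segment"] == int(GISegment.UNASSIGNED)).sum())
    if n_unassigned:
        logger.info("excluding %d unassigned rows from prevalence denominators", n_unassigned)
    return df[df["gi_segment"] != int(GISegment.UNASSIGNED)]


def weighted_prevalence(
    segmented: pd.DataFrame, weight_col: str = "weight"
) -> pd.DataFrame:
    """Weighted GI-segment proportions split by any-CF, per country-wave.

    Returns a tidy frame with columns ``country, wave, gi_segment, any_cf,
    proportion, effective_n``; within each country-wave the proportions sum
    to 1 over assigned segments.  ``any_cf`` missing is treated as False
    for the split (the segment-level proportion is unaffected).
    """
    df = _prepare(segmented, weight_col)
    if df.empty:
        raise ValueError("no assigned observations to tabulate")
    df = df.assign(any_cf=df["any_cf"].map(lambda v: bool(v) if v is not None and v == v else False))
    rows = []
    for (country, wave), grp in df.groupby(["country", "wave"]):
        total = grp[weight_col].sum()
        if total <= 0:
            raise ValueError(f"all-zero weights in cell country={country}, wave={wave}")
        for (seg, cf), sub in grp.groupby(["gi_segment", "any_cf"]):
            rows.append(
                {
                    "country": country,
                    "wave": wave,
                    "gi_segment": int(seg),
                    "any_cf": bool(cf),
                    "proportion": sub[weight_col].sum() / total,
                    "effective_n": len(grp),
                }
            )
    return pd.DataFrame(rows)


def high_needs_shares(prevalence_table: pd.DataFrame) -> pd.DataFrame:
    """Per country-wave weighted share in the two most severe GI segments."""
    tbl = prevalence_table.copy()
    tbl["high"] = tbl["gi_segment"].isin(HIGH_NEEDS_INTS)
    out = (
        tbl.groupby(["country", "wave"])
        .apply(lambda g: g.loc[g["high"], "proportion"].sum(), include_groups=False)
        .rename("high_needs_share")
        .reset_index()
    )
    return out


def rank_countries(prevalence_table: pd.DataFrame, wave: int) -> pd.DataFrame:
    """Rank countries ascending by high-needs share at the target wave.

    A country missing the target wave contributes its most recent earlier
    wave instead (latest-available rule).  Ties are broken by country name;
    both the share and the wave actually used are returned.
    """
    if prevalence_table.empty:
        raise ValueError("empty prevalence table")
    shares = high_needs_shares(prevalence_table)
    rows = []
    for country, grp in shares.groupby("country"):
        available = grp[grp["wave"] <= wave]
        if available.empty:
            logger.warning("country %s has no wave <= %d; skipped", country, wave)
            continue
        use = available.loc[available["wave"].idxmax()]
        rows.append({"country": country, "wave_used": int(use["wave"]),
                     "high_needs_share": float(use["high_needs_share"])})
    if not rows:
        raise ValueError(f"no country has data at or before wave {wave}")
    out = pd.DataFrame(rows).sort_values(
        ["high_needs_share", "country"], kind="mergesort"
    ).reset_index(drop=True)
    out.index = np.arange(1, len(out) + 1)
    out.index.name = "rank"
    return out


def plot_prevalence(prevalence_table: pd.DataFrame, wave: int, ax=None):
    """Stacked-bar chart of GI x CF composition per country, ranked by
    high-needs share (least severe countries first)."""
    import matplotlib.pyplot as plt

    ranking = rank_countries(prevalence_table, wave)
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 5))
    bottom = np.zeros(len(ranking))
    cmap = plt.get_cmap("RdYlGn_r")
    layers = [(seg, cf) for seg in range(1, 6) for cf in (False, True)]
    for i, (seg, cf) in enumerate(layers):
        vals = []
        for _, r in ranking.iterrows():
            sel = prevalence_table[
                (prevalence_table["country"] == r["country"])
                & (prevalence_table["wave"] == r["wave_used"])
                & (prevalence_table["gi_segment"] == seg)
                & (prevalence_table["any_cf"] == cf)
            ]
            vals.append(sel["proportion"].sum())
        vals = np.asarray(vals)
        ax.bar(
            ranking["country"], vals, bottom=bottom,
            color=cmap(i / (len(layers) - 1)),
            hatch="//" if cf else None,
            label=f"GI {seg}{' +CF' if cf else ''}",
        )
        bottom += vals
    ax.set_ylabel("weighted population share")
    ax.legend(fontsize=7, ncol=2)
    ax.tick_params(axis="x", rotation=60)
    return ax
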