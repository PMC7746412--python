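"""Phenotype and outcome coding rules used by the analysis.

Covers the derivation of weekly alcohol units from per-beverage intake
counts, the alcohol-sample exclusions, mid-point recoding of banded
household income, the registered outcome dichotomizations, and expression
of deprivation-index effects as a percentage of a decile.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ALCOHOL_UNITS_PER_DRINK", "INCOME_MIDPOINTS",
    "weekly_alcohol_units", "alcohol_exclusions", "income_midpoint",
    "dichotomize_outcome", "register_rule", "tdi_decile_scale",
]

#: nominal alcohol units (10 ml pure alcohol) assigned per reported drink
ALCOHOL_UNITS_PER_DRINK = {
    "red_wine": 1.75,               # 125 ml glass at 14%
    "white_wine_champagne": 1.75,   # 125 ml glass at 14%
    "beer_cider": 2.0,              # one pint, nominal
    "spirits": 1.0,                 # 25 ml standard measure at 40%
    "fortified_wine": 1.2,          # 60 ml at 20%
    "other": 1.0,                   # e.g. an alcopop
}

#: banded household income recoded to the band mid-point (open-ended bands
#: take a nominal value) so income can be analysed as a continuous outcome
INCOME_MIDPOINTS = {
    1: 15_000,    # < £18 000
    2: 24_500,    # £18 000 – £30 999
    3: 41_500,    # £31 000 – £51 999
    4: 76_000,    # £52 000 – £100 000
    5: 150_000,   # > £100 000
}

INCOME_HIGH_CUTOFF = 52_000  # dichotomized income: >= £52 000 vs below

MAX_WEEKLY_UNITS = 200  # implausible-intake exclusion threshold


def weekly_alcohol_units(intake: Mapping) -> float:
    """Average weekly alcohol units from per-beverage weekly drink counts.

    ``intake`` maps beverage types (keys of :data:`ALCOHOL_UNITS_PER_DRINK`)
    to weekly counts; absent beverages count as zero. Additive over
    beverages and linear in counts.
    """
    unknown = set(intake) - set(ALCOHOL_UNITS_PER_DRINK)
    if unknown:
        raise KeyError(f"unknown beverage types: {sorted(unknown)}")
    total = 0.0
    for bev, count in intake.items():
        if count is None or (isinstance(count, float) and np.isnan(count)):
            continue
        if count < 0:
            raise ValueError(f"negative count for {bev}: {count}")
        total += count * ALCOHOL_UNITS_PER_DRINK[bev]
    return total


def alcohol_exclusions(units, drinker_status) -> np.ndarray:
    """Inclusion mask for the alcohol-exposure sample.

    Excluded: self-reported former drinkers; implausibly high reported
    intake (> 200 units/week); and participants who are not never-drinkers
    but answered none of the intake questions (missing units). Never
    drinkers with zero units stay in.
    """
    units = pd.Series(units, dtype=float).reset_index(drop=True)
    status = pd.Series(drinker_status).reset_index(drop=True)
    if len(units) != len(status):
        raise ValueError("units and drinker_status lengths differ")
    known = {"never", "former", "current"}
    bad = set(status.dropna().unique()) - known
    if bad:
        raise ValueError(f"unknown drinker status values: {sorted(bad)}")
    include = np.ones(len(units), dtype=bool)
    include &= (status != "former").to_numpy()
    include &= ~(units > MAX_WEEKLY_UNITS).to_numpy()
    include &= ~(units.isna() & (status != "never")).to_numpy()
    n_excl = int((~include).sum())
    if n_excl:
        warnings.warn(f"alcohol exclusions removed {n_excl} participants")
    return include


def income_midpoint(category) -> np.ndarray | float:
    """Mid-point (nominal for open bands) of a banded income category."""
    if np.isscalar(category):
        cat = int(category)
        if cat not in INCOME_MIDPOINTS:
            raise KeyError(f"unknown income category {category!r}")
        return float(INCOME_MIDPOINTS[cat])
    s = pd.Series(category)
    out = np.full(len(s), np.nan)
    for i, v in enumerate(s):
        if pd.isna(v):
            continue
        out[i] = income_midpoint(v)
    return out


# ---------------------------------------------------------------------------
# dichotomization rules

_HAPPY = {"extremely happy", "very happy", "moderately happy"}
_UNHAPPY = {"moderately unhappy", "very unhappy", "extremely unhappy"}
_WEEKLY_OR_MORE = {"almost daily", "2-4 times a week", "about once a week"}
_LESS_THAN_WEEKLY = {"about once a month", "once every few months",
                     "never or almost never"}
_DEGREE = {"college or university degree"}
_LOWER_QUALS = {"a levels/as levels", "o levels/gcses", "cses",
                "nvq or hnd or hnc", "other professional qualifications",
                "none of the above"}


def _binary_from_sets(raw, positive, negative, rule_name):
    s = pd.Series(raw)
    out = np.full(len(s), np.nan)
    for i, v in enumerate(s):
        if pd.isna(v):
            continue
        v = str(v).strip().lower()
        if v in positive:
            out[i] = 1.0
        elif v in negative:
            out[i] = 0.0
        else:
            raise ValueError(f"value {v!r} not recognised by rule {rule_name!r}")
    return out


def _rule_income_high(raw):
    s = pd.Series(raw, dtype=float)
    out = np.where(s >= INCOME_HIGH_CUTOFF, 1.0, 0.0)
    return np.where(s.isna(), np.nan, out)


def _rule_tdi_top_third(raw):
    """Most deprived third versus the rest, cut at the empirical tertile."""
    s = pd.Series(raw, dtype=float)
    vals = s.dropna()
    if len(vals) == 0:
        raise ValueError("all deprivation values missing")
    cut = np.quantile(vals, 2.0 / 3.0)
    out = np.where(s > cut, 1.0, 0.0)
    return np.where(s.isna(), np.nan, out)


_RULES = {
    "income_high": _rule_income_high,
    "tdi_most_deprived_third": _rule_tdi_top_third,
    "frequency_weekly": lambda raw: _binary_from_sets(
        raw, _WEEKLY_OR_MORE, _LESS_THAN_WEEKLY, "frequency_weekly"),
    "happiness": lambda raw: _binary_from_sets(
        raw, _HAPPY, _UNHAPPY, "happiness"),
    "degree": lambda raw: _binary_from_sets(
        raw, _DEGREE, _LOWER_QUALS, "degree"),
}


def register_rule(name: str, func) -> None:
    """Register a custom dichotomization rule (vector → 1/0/NaN vector)."""
    _RULES[name] = func


def dichotomize_outcome(raw, rule: str) -> np.ndarray:
    """Apply a named dichotomization rule; missing always maps to missing."""
    if rule not in _RULES:
        raise KeyError(
            f"unknown dichotomization rule {rule!r}; known: {sorted(_RULES)}"
        )
    return np.asarray(_RULES[rule](raw), dtype=float)


def tdi_decile_scale(beta_tdi: float, tdi) -> float:
    """Express a deprivation-index effect as a percentage of one decile.

    The decile width is the mean gap between adjacent decile boundaries
    D1..D9, i.e. (P90 − P10)/8 — a declared convention (configurable via
    the boundaries argument of :func:`decile_width`).
    """
    return 100.0 * float(beta_tdi) / decile_width(tdi)


def decile_width(values, lower_pct: float = 10.0, upper_pct: float = 90.0) -> float:
    """Mean spacing of the empirical decile boundaries of ``values``."""
    v = pd.Series(values, dtype=float).dropna().to_numpy()
    if v.size == 0 or np.ptp(v) == 0:
        raise ValueError("degenerate (constant or empty) vector: no decile width")
    lo, hi = np.percentile(v, [lower_pct, upper_pct])
    n_gaps = (upper_pct - lower_pct) / 10.0
    return float((hi - lo) / n_gaps)
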