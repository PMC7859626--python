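"""Oxygen-exposure metrics and respiratory outcome labels.

Covers effective FiO2 for low-flow nasal cannula (dilution-corrected via a
shipped weight x flow grid), cumulative oxygen utilization over the first
14/28 days (area above room air in FiO2-excess.days), and the three outcome
labels: BPD by the Shennan criterion (supplemental oxygen at 36 weeks PMA,
birth weight < 1500 g), BPD by physiologic room-air challenge (>= 28
not-necessarily-consecutive days above room air plus a failed challenge),
and PRD (positive respiratory-morbidity domain on >= 2 of 4 caregiver
surveys in the first corrected year).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

ROOM_AIR = 0.21

SUPPORT_MODES = ("vent", "cpap", "high_flow", "low_flow_cannula", "room_air")


@dataclass
class OxygenTrace:
    """Daily respiratory flowsheet records for one subject.

    ``daily`` columns: day (1-based, strictly increasing), fio2 (fraction),
    support_mode, flow_lpm, pressure_cmH2O.  Missing days are allowed and
    handled by the gap policy in :func:`oxygen_auc`.
    """

    subject_id: str
    daily: pd.DataFrame
    birth_weight_g: float

    def __post_init__(self) -> None:
        days = self.daily["day"].to_numpy()
        if len(days) == 0:
            raise ValueError("trace covers no days")
        if days[0] < 1 or (np.diff(days) <= 0).any():
            raise ValueError("days must be strictly increasing, starting at 1")
        fio2 = self.daily["fio2"].to_numpy()
        if (fio2 < ROOM_AIR - 1e-9).any() or (fio2 > 1.0 + 1e-9).any():
            raise ValueError("FiO2 must be a fraction in [0.21, 1]")


def _load_conversion_table() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    with resources.files("preemiexpr.data").joinpath(
        "effective_fio2_low_flow.tsv"
    ).open() as fh:
        table = pd.read_csv(fh, sep="\t", comment="#")
    weights = table["weight_g"].to_numpy(dtype=float)
    flows = np.array([float(c) for c in table.columns[1:]])
    grid = table.iloc[:, 1:].to_numpy(dtype=float)
    return weights, flows, grid


_CONVERSION = None


def cannula_dilution_fraction(weight_g: float, flow_lpm: float) -> float:
    """Fraction of inspired gas supplied by the cannula, bilinear on the shipped grid."""
    global _CONVERSION
    if _CONVERSION is None:
        _CONVERSION = _load_conversion_table()
    weights, flows, grid = _CONVERSION
    w = float(np.clip(weight_g, weights[0], weights[-1]))
    q = float(np.clip(flow_lpm, flows[0], flows[-1]))
    iw = min(np.searchsorted(weights, w, side="right"), len(weights) - 1)
    jq = min(np.searchsorted(flows, q, side="right"), len(flows) - 1)
    iw0, jq0 = iw - 1, jq - 1
    tw = 0.0 if weights[iw] == weights[iw0] else (w - weights[iw0]) / (weights[iw] - weights[iw0])
    tq = 0.0 if flows[jq] == flows[jq0] else (q - flows[jq0]) / (flows[jq] - flows[jq0])
    top = grid[iw0, jq0] * (1 - tq) + grid[iw0, jq] * tq
    bot = grid[iw, jq0] * (1 - tq) + grid[iw, jq] * tq
    return float(top * (1 - tw) + bot * tw)


def effective_fio2(
    fio2: float,
    support_mode: str,
    flow_lpm: float = 0.0,
    weight_g: float = 1500.0,
) -> float:
    """Effective inspired oxygen fraction.

    Low-flow nasal cannula delivery is diluted by entrained room air; the
    correction interpolates the shipped weight x flow grid.  All other
    support modes pass the recorded FiO2 through unchanged.
    """
    if not ROOM_AIR - 1e-9 <= fio2 <= 1.0 + 1e-9:
        raise ValueError("FiO2 must be in [0.21, 1]")
    if flow_lpm < 0:
        raise ValueError("flow must be non-negative")
    if support_mode == "low_flow_cannula":
        frac = cannula_dilution_fraction(weight_g, flow_lpm)
        value = ROOM_AIR + (fio2 - ROOM_AIR) * frac
    else:
        value = fio2
    return float(np.clip(value, ROOM_AIR, 1.0))


def _effective_series(trace: OxygenTrace) -> pd.Series:
    eff = [
        effective_fio2(r.fio2, r.support_mode, r.flow_lpm, trace.birth_weight_g)
        for r in trace.daily.itertuples()
    ]
    return pd.Series(eff, index=trace.daily["day"].to_numpy())


def _fill_gaps(eff: pd.Series, through_day: int, locf_max: int = 2) -> np.ndarray:
    """Gap policy: carry the last observation forward up to ``locf_max`` days,
    then fall back to room air with a warning."""
    filled = np.full(through_day, np.nan)
    for day, value in eff.items():
        if 1 <= day <= through_day:
            filled[day - 1] = value
    last, age = np.nan, np.inf
    fell_back = False
    for i in range(through_day):
        if np.isnan(filled[i]):
            if age < locf_max and np.isfinite(last):
                filled[i] = last
                age += 1
            else:
                filled[i] = ROOM_AIR
                fell_back = True
        else:
            last, age = filled[i], 0
    if fell_back:
        warnings.warn("missing flowsheet days beyond carry-forward window treated as room air")
    return filled


def daily_excess_auc(effective: np.ndarray) -> float:
    """Default convention: sum of daily (effective FiO2 - 0.21)."""
    return float(np.sum(np.maximum(effective - ROOM_AIR, 0.0)))


#: named, swappable AUC conventions (a pressure-weighted variant can be registered)
AUC_CONVENTIONS: dict[str, Callable[[np.ndarray], float]] = {
    "daily_excess": daily_excess_auc,
}


def oxygen_auc(
    trace: OxygenTrace, through_day: int = 14, convention: str = "daily_excess"
) -> float:
    """Cumulative oxygen utilization over days 1..``through_day`` (FiO2-excess.days)."""
    if through_day < 1:
        raise ValueError("through_day must be >= 1")
    eff = _effective_series(trace)
    if not (eff.index <= through_day).any():
        raise ValueError("no flowsheet days within the requested window")
    filled = _fill_gaps(eff, through_day)
    return AUC_CONVENTIONS[convention](filled)


def label_bpd_shennan(support_at_36wk_pma: bool, birth_weight_g: float) -> str:
    """BPD by the Shennan criterion; not applicable at birth weight >= 1500 g."""
    if birth_weight_g >= 1500:
        return "not_applicable"
    return "yes" if support_at_36wk_pma else "no"


def qualifying_oxygen_days(trace: OxygenTrace) -> int:
    """Days with effective FiO2 above room air (adjacency irrelevant)."""
    eff = _effective_series(trace)
    return int((eff > ROOM_AIR + 1e-9).sum())


def label_bpd_rac(trace: OxygenTrace, rac_result: str) -> str:
    """Physiologic BPD: >= 28 qualifying oxygen days plus a failed room-air challenge.

    ``rac_result`` is one of pass/fail/not_done.  Ineligible subjects (fewer
    than 28 qualifying days) are labelled no regardless of challenge result;
    eligible subjects without a recorded challenge are not assessed.
    """
    if rac_result not in ("pass", "fail", "not_done"):
        raise ValueError("rac_result must be pass, fail or not_done")
    eligible = qualifying_oxygen_days(trace) >= 28
    if not eligible:
        return "no"
    if rac_result == "not_done":
        return "not_assessed"
    return "yes" if rac_result == "fail" else "no"


PRD_DOMAINS = ("hospitalization", "home_support", "respiratory_medication", "cough_wheeze")


def label_prd(surveys: Sequence[Optional[Mapping[str, bool]]]) -> str:
    """PRD from the 3/6/9/12-month caregiver surveys.

    yes iff at least two completed surveys each report >= 1 positive domain;
    no iff the positives plus the remaining missing surveys cannot reach two;
    missing otherwise.
    """
    if len(surveys) > 4:
        raise ValueError("at most four surveys")
    n_pos = sum(
        1 for s in surveys if s is not None and any(bool(s.get(d, False)) for d in PRD_DOMAINS)
    )
    n_missing = sum(1 for s in surveys if s is None) + (4 - len(surveys))
    if n_pos >= 2:
        return "yes"
    if n_pos + n_missing < 2:
        return "no"
    return "missing"


def label_subject(
    trace: OxygenTrace,
    support_at_36wk_pma: bool,
    rac_result: str,
    surveys: Sequence[Optional[Mapping[str, bool]]],
) -> dict:
    """All outcome labels plus Oxygen_AUC14/28 for one subject."""
    auc14 = oxygen_auc(trace, 14)
    auc28 = oxygen_auc(trace, 28)
    return {
        "subject_id": trace.subject_id,
        "bpd_shennan": label_bpd_shennan(support_at_36wk_pma, trace.birth_weight_g),
        "bpd_rac": label_bpd_rac(trace, rac_result),
        "prd": label_prd(surveys),
        "oxygen_auc14": auc14,
        "oxygen_auc28": auc28,
    }
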