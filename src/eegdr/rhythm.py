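"""Hormone circadian-rhythm classification and diurnal slope.

Plasma ACTH and cortisol (COR) are sampled at 08:00, 16:00 and 24:00.  A
healthy hypothalamic-pituitary-adrenal (HPA) profile falls steeply across
the day; a circadian-rhythm disturbance (CRD) is declared when a later
sample fails to drop below half of an earlier one:

    disturbed  <=>  c16 >= 0.5*c8  or  c24 >= 0.5*c16  or  c24 >= 0.5*c8

(threshold and rule subset configurable; the comparison is inclusive).

The diurnal cortisol slope is the decline rate from the morning to the
midnight draw, ``(c8 - c24) / 16 h`` (positive = declining); a three-point
least-squares definition is available and agrees exactly when the profile
is collinear in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import EstimationError, ParameterError, ValidationError

__all__ = [
    "HormoneProfile", "RhythmVerdict", "ALL_RULES",
    "classify_rhythm", "diurnal_slope", "cohort_incidence", "two_sample_t",
]

ALL_RULES = ("16v8", "24v16", "24v8")
_HOURS = {"c8": 8.0, "c16": 16.0, "c24": 24.0}


@dataclass
class HormoneProfile:
    """One analyte's three-timepoint concentrations for one subject.

    Units follow the assay convention: nmol/L for COR, pg/mL for ACTH.
    """
    subject_id: str
    analyte: str            # "ACTH" or "COR"
    c8: float
    c16: float
    c24: float

    def __post_init__(self) -> None:
        for name in ("c8", "c16", "c24"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"{self.subject_id}: {name} must be finite and > 0, got {v!r}")


@dataclass
class RhythmVerdict:
    disturbed: bool
    violated_rules: tuple[str, ...]
    ratios: dict[str, float]


def classify_rhythm(p: HormoneProfile, threshold: float = 0.5,
                    rules: Sequence[str] = ALL_RULES) -> RhythmVerdict:
    """Mark a profile disturbed when any later/earlier ratio is >= threshold."""
    if not 0 < threshold < 1:
        raise ParameterError("threshold must be in (0, 1)")
    unknown = set(rules) - set(ALL_RULES)
    if unknown:
        raise ParameterError(f"unknown rule(s): {sorted(unknown)}")
    ratios = {"16v8": p.c16 / p.c8, "24v16": p.c24 / p.c16, "24v8": p.c24 / p.c8}
    violated = tuple(r for r in rules if ratios[r] >= threshold)
    return RhythmVerdict(disturbed=bool(violated), violated_rules=violated, ratios=ratios)


def diurnal_slope(p: HormoneProfile, method: str = "two_point") -> float:
    """Decline rate in concentration units per hour (positive = declining).

    ``two_point``: (c8 - c24) / 16 h.  ``regression``: negative slope of the
    least-squares line through (8h, c8), (16h, c16), (24h, c24).
    """
    if method == "two_point":
        return (p.c8 - p.c24) / 16.0
    if method == "regression":
        t = np.array([_HOURS["c8"], _HOURS["c16"], _HOURS["c24"]])
        c = np.array([p.c8, p.c16, p.c24])
        slope, _ = np.polyfit(t, c, 1)
        return -float(slope)
    raise ParameterError(f"unknown slope method {method!r}")


def cohort_incidence(profiles: Iterable[HormoneProfile], groups: Sequence,
                     threshold: float = 0.5, rules: Sequence[str] = ALL_RULES,
                     continuity_correction: bool = False) -> dict:
    """Per-group, per-analyte disturbance incidence with a 2x2 chi-square.

    Returns a dict with ``incidence`` (analyte -> group -> fraction),
    ``tables`` (analyte -> 2x2 disturbed-by-group counts), and ``chi2`` /
    ``p_value`` per analyte (Pearson, uncorrected by default).
    """
    profiles = list(profiles)
    groups = list(groups)
    if len(profiles) != len(groups):
        raise ParameterError("profiles and groups must align")
    if not profiles:
        raise EstimationError("empty cohort")
    df = pd.DataFrame({
        "analyte": [p.analyte for p in profiles],
        "group": groups,
        "disturbed": [classify_rhythm(p, threshold, rules).disturbed for p in profiles],
    })
    out: dict = {"incidence": {}, "tables": {}, "chi2": {}, "p_value": {}}
    for analyte, sub in df.groupby("analyte"):
        counts = sub.groupby("group")["disturbed"].agg(["sum", "count"])
        if (counts["count"] == 0).any() or len(counts) == 0:
            raise EstimationError(f"{analyte}: empty group")
        out["incidence"][analyte] = (counts["sum"] / counts["count"]).to_dict()
        if len(counts) == 2:
            table = np.array([
                [counts["sum"].iloc[0], counts["count"].iloc[0] - counts["sum"].iloc[0]],
                [counts["sum"].iloc[1], counts["count"].iloc[1] - counts["sum"].iloc[1]],
            ])
            out["tables"][analyte] = table
            chi2, p = _pearson_chi2_2x2(table, continuity_correction)
            out["chi2"][analyte] = chi2
            out["p_value"][analyte] = p
    return out


def _pearson_chi2_2x2(table: np.ndarray, correction: bool) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table; 0 when a margin is empty
    (degenerate table carries no association evidence)."""
    O = np.asarray(table, float)
    total = O.sum()
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / total
    if np.any(E == 0):
        return 0.0, 1.0
    d = np.abs(O - E)
    if correction:
        d = np.maximum(d - 0.5, 0.0)
    chi2 = float(np.sum(d ** 2 / E))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def two_sample_t(a: Sequence[float], b: Sequence[float], equal_var: bool = True) -> dict:
    """Thin two-sample t-test wrapper for the group-comparison harness."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                           equal_var=equal_var)
    return {"t": float(t), "p": float(p)}
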