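"""Deterministic scoring for HAMD-24 and TAS-20.

HAMD-24 (24-item Hamilton Depression Rating Scale)
--------------------------------------------------
Clinician-rated severity. Total = sum of the 24 items. Severity bands:
total > 35 severe; 20–35 definite depression; 8–19 possible depression;
< 8 normal (the 8/20 boundaries are half-open upward and configurable).
Factor subscores are sums over a 7-factor item map. The anxious-depression
subtype gate uses the anxiety/somatization factor: score >= 7 -> A-MDD
(depression with anxiety), <= 2 -> NA-MDD (without), 3–6 indeterminate.

The shipped item->factor map and per-item ranges follow the standard
7-factor HAMD-24 structure (externally sourced convention, editable via
:class:`HamdConfig`): items 4,5,6,12,13,14,16,17,18,21 are rated 0–2, the
rest 0–4.

TAS-20 (Toronto Alexithymia Scale)
----------------------------------
Self-report, 20 items on a 1–5 Likert scale; items 4, 5, 10, 18, 19 are
reverse-scored (v -> 6 - v). Total in [20, 100]. Factors partition the
items exactly: DIF (difficulty identifying feelings) = {1,3,6,7,9,13,14},
DDF (difficulty describing feelings) = {2,4,11,12,17}, EOT (externally
oriented thinking) = {5,8,10,15,16,18,19,20}. Bands: total <= 51
non-alexithymia, 52–60 moderate, >= 61 severe.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._errors import ParameterError, ValidationError

__all__ = [
    "HamdConfig", "DEFAULT_HAMD_CONFIG", "ScaleResult",
    "score_hamd", "classify_anxiety_subtype", "score_tas", "batch_score",
    "hamd_item_ranges", "TAS_N_ITEMS", "TAS_REVERSE_ITEMS", "TAS_FACTORS",
]

HAMD_N_ITEMS = 24
TAS_N_ITEMS = 20
TAS_REVERSE_ITEMS = frozenset({4, 5, 10, 18, 19})
TAS_FACTORS = {
    "DIF": (1, 3, 6, 7, 9, 13, 14),
    "DDF": (2, 4, 11, 12, 17),
    "EOT": (5, 8, 10, 15, 16, 18, 19, 20),
}


@dataclass(frozen=True)
class HamdConfig:
    """Editable HAMD-24 scoring configuration (item ranges, factors, bands)."""
    narrow_items: frozenset[int] = frozenset({4, 5, 6, 12, 13, 14, 16, 17, 18, 21})
    factor_map: dict = field(default_factory=lambda: {
        "anxiety_somatization": (10, 11, 12, 13, 15, 17),
        "weight": (16,),
        "cognitive_impairment": (2, 3, 9, 19, 20, 21),
        "diurnal_variation": (18,),
        "retardation": (1, 7, 8, 14),
        "sleep_disturbance": (4, 5, 6),
        "hopelessness": (22, 23, 24),
    })
    severe_above: int = 35       # total >  35 -> severe
    definite_from: int = 20      # total >= 20 -> definite
    possible_from: int = 8       # total >=  8 -> possible


DEFAULT_HAMD_CONFIG = HamdConfig()


def hamd_item_ranges(config: HamdConfig = DEFAULT_HAMD_CONFIG) -> list[tuple[int, int]]:
    """(min, max) admissible score per item, 1-based order."""
    return [(0, 2) if (i + 1) in config.narrow_items else (0, 4)
            for i in range(HAMD_N_ITEMS)]


@dataclass
class ScaleResult:
    total: int
    factor_scores: dict[str, int]
    band: str


def _validate_items(items, n_expected: int, ranges: list[tuple[int, int]]) -> list[int]:
    items = list(items)
    if len(items) != n_expected:
        raise ValidationError(f"expected {n_expected} items, got {len(items)}")
    out = []
    for i, v in enumerate(items):
        iv = int(v)
        if iv != v:
            raise ValidationError(f"item {i + 1}: non-integer score {v!r}")
        lo, hi = ranges[i]
        if not lo <= iv <= hi:
            raise ValidationError(f"item {i + 1}: score {iv} outside [{lo}, {hi}]")
        out.append(iv)
    return out


def score_hamd(items, config: HamdConfig = DEFAULT_HAMD_CONFIG) -> ScaleResult:
    """Total, 7-factor subscores and severity band for a HAMD-24 response."""
    vals = _validate_items(items, HAMD_N_ITEMS, hamd_item_ranges(config))
    total = sum(vals)
    factors = {name: sum(vals[i - 1] for i in idx)
               for name, idx in config.factor_map.items()}
    if total > config.severe_above:
        band = "severe"
    elif total >= config.definite_from:
        band = "definite"
    elif total >= config.possible_from:
        band = "possible"
    else:
        band = "normal"
    return ScaleResult(total=total, factor_scores=factors, band=band)


def classify_anxiety_subtype(items, config: HamdConfig = DEFAULT_HAMD_CONFIG) -> str:
    """Anxiety/somatization subtype gate: >=7 A-MDD, <=2 NA-MDD, else indeterminate."""
    if "anxiety_somatization" not in config.factor_map:
        raise ParameterError("factor map lacks 'anxiety_somatization'")
    score = score_hamd(items, config).factor_scores["anxiety_somatization"]
    if score >= 7:
        return "A-MDD"
    if score <= 2:
        return "NA-MDD"
    return "indeterminate"


def score_tas(items) -> ScaleResult:
    """Total, DIF/DDF/EOT factors and alexithymia band for a TAS-20 response.

    Reverse items (4, 5, 10, 18, 19) are mapped v -> 6 - v before summation;
    factor scores are computed on the reversed values and partition the total.
    """
    vals = _validate_items(items, TAS_N_ITEMS, [(1, 5)] * TAS_N_ITEMS)
    scored = [6 - v if (i + 1) in TAS_REVERSE_ITEMS else v
              for i, v in enumerate(vals)]
    total = sum(scored)
    factors = {name: sum(scored[i - 1] for i in idx)
               for name, idx in TAS_FACTORS.items()}
    assert sum(factors.values()) == total  # factors partition items exactly
    if total >= 61:
        band = "severe"
    elif total >= 52:
        band = "moderate"
    else:
        band = "non-alexithymia"
    return ScaleResult(total=total, factor_scores=factors, band=band)


def batch_score(table: pd.DataFrame | str | Path, instrument: str,
                config: HamdConfig = DEFAULT_HAMD_CONFIG) -> pd.DataFrame:
    """Score a cohort table (columns item_1..item_K) row by row.

    Malformed rows are reported in the ``status`` column with their row
    number; valid rows are still scored.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    instrument = instrument.lower()
    if instrument == "hamd":
        n_items, scorer = HAMD_N_ITEMS, lambda it: score_hamd(it, config)
    elif instrument == "tas":
        n_items, scorer = TAS_N_ITEMS, score_tas
    else:
        raise ParameterError(f"unknown instrument {instrument!r}")
    cols = [f"item_{i + 1}" for i in range(n_items)]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValidationError(f"table lacks item columns: {missing}")
    out = []
    for rownum, (_, row) in enumerate(table.iterrows()):
        rec = {"row": rownum}
        if "subject_id" in table.columns:
            rec["subject_id"] = row["subject_id"]
        try:
            res = scorer([row[c] for c in cols])
        except ValidationError as exc:
            rec.update(status=f"error: {exc}", total=pd.NA, band=pd.NA)
        else:
            rec.update(status="ok", total=res.total, band=res.band,
                       **{f"factor_{k}": v for k, v in res.factor_scores.items()})
            if instrument == "hamd":
                rec["subtype"] = classify_anxiety_subtype([row[c] for c in cols], config)
        out.append(rec)
    return pd.DataFrame(out)
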