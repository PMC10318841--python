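"""N-ML-MAP-P: a five-item, 5-star quality checklist for neuroimaging-based
psychiatric ML classifier studies, implemented as a configurable scoring
engine.

The five items cover sampling representativeness (sample size and number of
sites), model-performance estimation (cross-validation scheme), model
generalizability (external validation), reporting transparency (which
secondary performance metrics are reported) and model reproducibility
(data/model availability).  The default rubric scores each item 0–2 points
(total 0–10, stars = total/2 rounded to the half-star grid with a 0.5-star
floor); every rule and the star map can be replaced via a JSON/YAML rubric
file, so alternative point tables can be dropped in without code changes.

Missing information never raises: "not reported" scores the item floor and is
flagged — the same transparency penalty risk-of-bias tools apply.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .evidence import EvidenceTable, StudyRecord, SECONDARY_METRICS

__all__ = [
    "Rubric",
    "RubricItem",
    "QualityScore",
    "default_rubric",
    "score_study",
    "score_table",
    "adjudicate",
]


@dataclass(frozen=True)
class RubricItem:
    id: str
    name: str
    rule: str           # key into the rule registry
    max_points: float
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Rubric:
    items: tuple[RubricItem, ...]
    #: 'half_floor' maps total -> max(0.5, floor(total+0.5)/2); or a list of
    #: [threshold, stars] breakpoints applied as a step function
    star_map: object = "half_floor"

    def __post_init__(self):
        if len(self.items) != 5:
            raise ValueError(f"a rubric must have exactly 5 items, got {len(self.items)}")

    @property
    def max_total(self) -> float:
        return sum(i.max_points for i in self.items)

    def stars(self, total: float) -> float:
        if self.star_map == "half_floor":
            return max(0.5, math.floor(total + 0.5) / 2.0)
        best = 0.5
        for threshold, stars in sorted(self.star_map):  # type: ignore[arg-type]
            if total >= threshold:
                best = stars
        return best

    @classmethod
    def from_file(cls, path) -> "Rubric":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        items = tuple(RubricItem(**it) for it in raw["items"])
        return cls(items=items, star_map=raw.get("star_map", "half_floor"))

    def to_file(self, path) -> None:
        raw = {"items": [vars(i) for i in self.items], "star_map": self.star_map}
        Path(path).write_text(json.dumps(raw, indent=2))


# --- rule registry ---------------------------------------------------------

def _rule_sample(rec: StudyRecord, params: dict) -> tuple[float, Optional[str]]:
    n_large = params.get("n_large", 200)
    n = rec.n_total if rec.n_total else (rec.n_patients + rec.n_controls)
    multi = rec.n_sites >= params.get("multi_site_min", 2)
    large = n is not None and n >= n_large
    return float(large) + float(multi), None


def _rule_cv(rec: StudyRecord, params: dict) -> tuple[float, Optional[str]]:
    table = params.get("points", {"none": 0, "other": 0, "LOOCV": 1, "kfold": 2, "nested_kfold": 2})
    if rec.cv_scheme not in table:
        return 0.0, "cv_scheme not reported"
    return float(table[rec.cv_scheme]), None


def _rule_external(rec: StudyRecord, params: dict) -> tuple[float, Optional[str]]:
    table = params.get("points", {"none": 0, "within_country": 1, "cross_country": 2})
    if rec.external_validation not in table:
        return 0.0, "external_validation not reported"
    return float(table[rec.external_validation]), None


def _rule_reporting(rec: StudyRecord, params: dict) -> tuple[float, Optional[str]]:
    per_metric = params.get("points_per_metric", 0.5)
    cap = params.get("cap", 2.0)
    count = len(set(rec.reported_metrics) & set(SECONDARY_METRICS))
    flag = "no secondary metrics reported" if count == 0 else None
    return min(cap, count * per_metric), flag


def _rule_availability(rec: StudyRecord, params: dict) -> tuple[float, Optional[str]]:
    if rec.data_verified or rec.model_verified:
        return 2.0, None
    if rec.data_claimed or rec.model_claimed:
        return 1.0, None
    return 0.0, "no availability statement"


_RULES: dict[str, Callable[[StudyRecord, dict], tuple[float, Optional[str]]]] = {
    "sample_representativeness": _rule_sample,
    "cv_scheme": _rule_cv,
    "external_validation": _rule_external,
    "reporting_transparency": _rule_reporting,
    "availability": _rule_availability,
}


def default_rubric() -> Rubric:
    """The built-in 0–10 point table (each item 0–2).

    item 1: 1 point for n ≥ 200, 1 point for multi-site acquisition;
    item 2: none/other 0, LOOCV 1, k-fold/nested k-fold 2;
    item 3: no external validation 0, within-country 1, cross-country 2;
    item 4: half a point per reported secondary metric (sensitivity,
            specificity, balanced accuracy, AUC), capped at 2;
    item 5: availability verified 2, claimed 1, absent 0.
    """
    return Rubric(items=(
        RubricItem("item1", "sampling representativeness", "sample_representativeness", 2.0),
        RubricItem("item2", "model performance estimation", "cv_scheme", 2.0),
        RubricItem("item3", "model generalizability", "external_validation", 2.0),
        RubricItem("item4", "reporting transparency", "reporting_transparency", 2.0),
        RubricItem("item5", "model reproducibility", "availability", 2.0),
    ))


@dataclass(frozen=True)
class QualityScore:
    study_id: str
    per_item: tuple[float, ...]
    total: float
    stars: float
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["per_item"] = list(self.per_item)
        d["flags"] = list(self.flags)
        return d


def score_study(record: StudyRecord, rubric: Optional[Rubric] = None) -> QualityScore:
    """Apply the rubric to one record; deterministic, never raises on missing
    fields (they score the floor and are flagged)."""
    rubric = rubric or default_rubric()
    points: list[float] = []
    flags: list[str] = []
    for item in rubric.items:
        rule = _RULES.get(item.rule)
        if rule is None:
            raise ValueError(f"unknown rubric rule {item.rule!r}")
        pts, flag = rule(record, item.params)
        pts = max(0.0, min(pts, item.max_points))
        points.append(pts)
        if flag:
            flags.append(f"{item.id}: {flag}")
    total = float(sum(points))
    return QualityScore(study_id=record.study_id, per_item=tuple(points),
                        total=total, stars=rubric.stars(total), flags=tuple(flags))


def score_table(
    table: EvidenceTable,
    rubric: Optional[Rubric] = None,
    low_quality_stars: float = 3.0,
) -> tuple[list[QualityScore], dict]:
    """Score every record and summarise: mean total by year and by disorder,
    plus the share of studies rated below the low-quality star cutoff."""
    if len(table) == 0:
        raise ValueError("empty evidence table")
    rubric = rubric or default_rubric()
    scores = [score_study(r, rubric) for r in table.records]
    df = pd.DataFrame({
        "study_id": [s.study_id for s in scores],
        "year": [r.year for r in table.records],
        "disorder": [r.disorder for r in table.records],
        "total": [s.total for s in scores],
        "stars": [s.stars for s in scores],
    })
    summary = {
        "n": len(scores),
        "mean_total": float(df["total"].mean()),
        "mean_stars": float(df["stars"].mean()),
        "mean_total_by_year": {int(y): float(v) for y, v in df.groupby("year")["total"].mean().items()},
        "mean_total_by_disorder": {str(k): float(v) for k, v in df.groupby("disorder")["total"].mean().items()},
        "low_quality_cutoff_stars": low_quality_stars,
        "share_low_quality": float((df["stars"] < low_quality_stars).mean()),
    }
    return scores, summary


def adjudicate(score_a: QualityScore, score_b: QualityScore, threshold: float = 2.0) -> bool:
    """True when two raters' totals differ by strictly more than ``threshold``
    points, i.e. a third independent rater is needed."""
    if score_a.study_id != score_b.study_id:
        raise ValueError("adjudication requires scores for the same study")
    return abs(score_a.total - score_b.total) > threshold
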