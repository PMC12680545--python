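"""The Bone Strength Index (BSI) and the fracture-prediction rule.

BSI = femoral strength / maximum sideways-fall impact force.  A femur is
predicted to fracture in a sideways fall when its BSI is strictly less
than one: the boundary BSI = 1 is classified as non-fracture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .impact import ImpactModelSet, Metric, max_impact_force

__all__ = ["SubjectRecord", "BSIResult", "compute_bsi", "evaluate_subject",
           "evaluate_cohort", "metric_attribution"]


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's metrics, group label and FE-derived strength.

    Units: age years, weight kg, height m, STT mm, strength kN.  Clinical
    metadata (DXA T/Z-scores, BMD, FRAX) travels untouched in ``metadata``.
    """

    id: str
    group: str
    age_years: float
    weight_kg: float
    height_m: float
    stt_mm: float
    strength_kN: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("fracture", "control"):
            raise ValueError("group must be 'fracture' or 'control'")
        for name in ("age_years", "weight_kg", "height_m", "stt_mm",
                     "strength_kN"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite")

    def metrics(self) -> dict:
        return {"age": self.age_years, "weight": self.weight_kg,
                "height": self.height_m, "stt": self.stt_mm}


@dataclass(frozen=True)
class BSIResult:
    """BSI outcome for one subject."""

    bsi: float
    strength_kN: float
    max_force_kN: float
    argmax_metric: Metric | None
    per_metric_forces: dict
    predicted_fracture: bool
    subject_id: str | None = None

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "bsi": self.bsi,
            "strength_kN": self.strength_kN,
            "max_force_kN": self.max_force_kN,
            "argmax_metric": (self.argmax_metric.value
                              if self.argmax_metric else None),
            "per_metric_forces": {m.value: f
                                  for m, f in self.per_metric_forces.items()},
            "predicted_fracture": self.predicted_fracture,
        }


def compute_bsi(strength_kN: float, max_force_kN: float) -> BSIResult:
    """Exact strength / max-force ratio with the strict BSI < 1 rule."""
    if not (math.isfinite(strength_kN) and strength_kN > 0):
        raise ValueError("strength must be positive and finite")
    if not (math.isfinite(max_force_kN) and max_force_kN > 0):
        raise ValueError("max impact force must be positive and finite")
    bsi = strength_kN / max_force_kN
    return BSIResult(bsi=bsi, strength_kN=strength_kN,
                     max_force_kN=max_force_kN, argmax_metric=None,
                     per_metric_forces={}, predicted_fracture=bsi < 1.0)


def evaluate_subject(record: SubjectRecord,
                     model_set: ImpactModelSet) -> BSIResult:
    """Per-metric forces, maximum impact force and BSI for one subject."""
    forces = model_set.per_metric_forces(record.metrics())
    force, metric = max_impact_force(model_set, record.metrics())
    base = compute_bsi(record.strength_kN, force)
    return BSIResult(bsi=base.bsi, strength_kN=record.strength_kN,
                     max_force_kN=force, argmax_metric=metric,
                     per_metric_forces=forces,
                     predicted_fracture=base.predicted_fracture,
                     subject_id=record.id)


def evaluate_cohort(cohort: pd.DataFrame,
                    model_set: ImpactModelSet) -> pd.DataFrame:
    """BSI results for a cohort table.

    Expects the cohort CSV columns (id, group, age_years, weight_kg,
    height_m, stt_mm, strength_kN); extra columns are carried through as
    metadata.  Returns one row per subject with the cohort columns plus
    per-metric forces, max force, argmax metric, BSI and the prediction.
    """
    required = {"id", "group", "age_years", "weight_kg", "height_m",
                "stt_mm", "strength_kN"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    extra = [c for c in cohort.columns if c not in required]
    rows = []
    for _, row in cohort.iterrows():
        record = SubjectRecord(
            id=str(row["id"]), group=str(row["group"]),
            age_years=float(row["age_years"]),
            weight_kg=float(row["weight_kg"]),
            height_m=float(row["height_m"]), stt_mm=float(row["stt_mm"]),
            strength_kN=float(row["strength_kN"]),
            metadata={c: row[c] for c in extra},
        )
        res = evaluate_subject(record, model_set)
        out = {
            "id": record.id, "group": record.group,
            "age_years": record.age_years, "weight_kg": record.weight_kg,
            "height_m": record.height_m, "stt_mm": record.stt_mm,
            "strength_kN": record.strength_kN,
            "max_force_kN": res.max_force_kN,
            "argmax_metric": res.argmax_metric.value,
            "bsi": res.bsi,
            "predicted_fracture": res.predicted_fracture,
        }
        for m, f in res.per_metric_forces.items():
            out[f"force_{m.value}_kN"] = f
        for c in extra:
            out[c] = row[c]
        rows.append(out)
    return pd.DataFrame(rows)


def metric_attribution(results: pd.DataFrame) -> pd.DataFrame:
    """Which metric produced each subject's maximum impact force.

    Returns one row per metric with per-group counts, the overall count
    and the overall percentage (percentages sum to 100 up to rounding).
    """
    if results.empty:
        raise ValueError("no results to attribute")
    order = [m.value for m in Metric]
    groups = sorted(results["group"].unique())
    rows = []
    total = len(results)
    for metric in order:
        sel = results["argmax_metric"] == metric
        row = {"metric": metric}
        for g in groups:
            row[f"count_{g}"] = int((sel & (results["group"] == g)).sum())
        row["count"] = int(sel.sum())
        row["percent"] = 100.0 * sel.sum() / total
        rows.append(row)
    return pd.DataFrame(rows)
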