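"""Univariate linear models of sideways-fall impact force.

The peak force transmitted to the proximal femur during a sideways fall
from standing height scales, to first order, linearly with simple patient
metrics: age, body weight, standing height and trochanteric soft-tissue
thickness (STT).  This module represents those one-variable force models
(force in kN), fits them to literature data by ordinary least squares,
averages models across studies, recovers them exactly from published
group summaries (linear maps commute with medians, quartiles and standard
deviations), and evaluates the per-subject *maximum* impact force across
whichever metrics are available.

Two named coefficient sets ship with the package:

``as_printed``
    The four univariate equations exactly as published (weight in newtons).
``table_reconciled``
    Models recovered from the published cohort summary tables.  The age,
    weight and height lines are fixed by the control group's quartile
    pairs; the STT line by the control mean/SD pair with a negative slope
    (thicker soft tissue attenuates impact).  This set reproduces the
    published group-level force summaries to within about 0.01-0.04 kN and
    is the default for BSI computation.
"""

from __future__ import annotations

import csv
import json
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from scipy import stats as _stats

__all__ = [
    "Metric",
    "Unit",
    "LinearImpactModel",
    "LiteratureStudy",
    "ImpactModelSet",
    "SummaryPoint",
    "evaluate_model",
    "fit_points",
    "aggregate_models",
    "recover_from_two_points",
    "recover_from_mean_sd",
    "max_impact_force",
    "as_printed",
    "table_reconciled",
    "builtin_model_set",
    "model_set_to_json",
    "model_set_from_json",
    "load_literature_studies",
    "aggregate_studies",
    "GRAVITY",
]

#: Standard gravity used when translating body mass [kg] to weight [N].
GRAVITY = 9.81


class Metric(str, Enum):
    AGE = "age"
    WEIGHT = "weight"
    HEIGHT = "height"
    STT = "stt"


class Unit(str, Enum):
    YEARS = "years"
    KG = "kg"
    NEWTONS = "N"
    M = "m"
    MM = "mm"


#: Units a model may legally carry for each metric.
ALLOWED_UNITS: dict[Metric, tuple[Unit, ...]] = {
    Metric.AGE: (Unit.YEARS,),
    Metric.WEIGHT: (Unit.KG, Unit.NEWTONS),
    Metric.HEIGHT: (Unit.M,),
    Metric.STT: (Unit.MM,),
}

#: Canonical unit in which subject metrics are supplied to `max_impact_force`.
CANONICAL_UNITS: dict[Metric, Unit] = {
    Metric.AGE: Unit.YEARS,
    Metric.WEIGHT: Unit.KG,
    Metric.HEIGHT: Unit.M,
    Metric.STT: Unit.MM,
}

#: Fixed metric order used for deterministic tie-breaking.
METRIC_ORDER: tuple[Metric, ...] = (
    Metric.AGE,
    Metric.WEIGHT,
    Metric.HEIGHT,
    Metric.STT,
)


def _as_metric(metric: Metric | str) -> Metric:
    return metric if isinstance(metric, Metric) else Metric(str(metric).lower())


@dataclass(frozen=True)
class LinearImpactModel:
    """One univariate impact-force model ``F[kN] = slope * x + intercept``."""

    metric: Metric
    slope: float
    intercept: float
    metric_unit: Unit
    provenance: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "metric", _as_metric(self.metric))
        object.__setattr__(self, "metric_unit", Unit(self.metric_unit))
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ValueError("slope and intercept must be finite")
        if self.metric_unit not in ALLOWED_UNITS[self.metric]:
            raise ValueError(
                f"unit {self.metric_unit.value!r} is not valid for metric "
                f"{self.metric.value!r}"
            )

    def evaluate(self, x: float, unit: Unit | str | None = None) -> float:
        """Predicted impact force in kN at metric value ``x``.

        ``unit`` optionally declares the unit of ``x``; a mismatch with the
        model's unit is rejected rather than silently converted.
        """
        if unit is not None and Unit(unit) != self.metric_unit:
            raise ValueError(
                f"value given in {Unit(unit).value!r} but model expects "
                f"{self.metric_unit.value!r}"
            )
        x = float(x)
        if not math.isfinite(x):
            raise ValueError("metric value must be finite")
        return self.slope * x + self.intercept

    def to_dict(self) -> dict:
        return {
            "metric": self.metric.value,
            "slope": self.slope,
            "intercept": self.intercept,
            "metric_unit": self.metric_unit.value,
            "provenance": self.provenance,
        }


def evaluate_model(
    model: LinearImpactModel, x: float, unit: Unit | str | None = None
) -> float:
    """Functional alias for :meth:`LinearImpactModel.evaluate`."""
    return model.evaluate(x, unit=unit)


@dataclass(frozen=True)
class SummaryPoint:
    """A published (metric value, force) summary pair.

    ``kind`` records whether the pair is a median, quartile or mean; for
    mean summaries an optional ``sd_pair`` carries (metric SD, force SD).
    """

    metric: Metric
    x: float
    F: float
    kind: str = "median"
    sd_pair: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "metric", _as_metric(self.metric))
        if self.kind not in ("median", "quartile", "mean"):
            raise ValueError(f"unknown summary kind {self.kind!r}")
        if not self.F > 0:
            raise ValueError("summary force must be positive")
        if self.sd_pair is not None:
            x_sd, f_sd = self.sd_pair
            if not (x_sd > 0 and f_sd > 0):
                raise ValueError("sd_pair values must be positive")


@dataclass(frozen=True)
class LiteratureStudy:
    """One literature source: raw (x, F) points and/or a reported line."""

    metric: Metric
    label: str
    n_samples: int
    points: tuple[tuple[float, float], ...] | None = None
    model: LinearImpactModel | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "metric", _as_metric(self.metric))
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.points is None and self.model is None:
            raise ValueError("study needs points and/or a model")

    def as_model(self, metric_unit: Unit | None = None) -> LinearImpactModel:
        """The study's line, fitting the points if no line was reported."""
        if self.model is not None:
            return self.model
        unit = metric_unit or CANONICAL_UNITS[self.metric]
        return fit_points(self.metric, self.points, metric_unit=unit)


def fit_points(
    metric: Metric | str,
    points: Sequence[tuple[float, float]],
    metric_unit: Unit | str | None = None,
) -> LinearImpactModel:
    """Ordinary least-squares line through (x, F) points.

    Minimises the vertical squared error, exactly as when estimating a
    study's force model from points read off a correlation plot.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (x, F) points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("all x values identical: degenerate design")
    res = _stats.linregress(x, y)
    metric = _as_metric(metric)
    unit = Unit(metric_unit) if metric_unit is not None else CANONICAL_UNITS[metric]
    return LinearImpactModel(metric, float(res.slope), float(res.intercept), unit, "fitted")


def aggregate_models(
    models: Sequence[LinearImpactModel],
    weights: Sequence[float] | None = None,
) -> LinearImpactModel:
    """Average slopes and intercepts across studies of one metric.

    Unweighted arithmetic mean by default; sample-size weighting is
    available as an opt-in refinement.
    """
    if len(models) == 0:
        raise ValueError("no models to aggregate")
    metrics = {m.metric for m in models}
    units = {m.metric_unit for m in models}
    if len(metrics) != 1 or len(units) != 1:
        raise ValueError("models must share metric and metric unit")
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(models),) or np.any(w <= 0):
            raise ValueError("weights must be positive, one per model")
    else:
        w = None
    slope = float(np.average([m.slope for m in models], weights=w))
    intercept = float(np.average([m.intercept for m in models], weights=w))
    return LinearImpactModel(
        models[0].metric, slope, intercept, models[0].metric_unit, "aggregated"
    )


def recover_from_two_points(
    p1: SummaryPoint,
    p2: SummaryPoint,
    metric_unit: Unit | str | None = None,
) -> LinearImpactModel:
    """Exact line through two published summary pairs.

    Because a linear map commutes with order statistics, the line through
    e.g. the control group's (age quartile, force quartile) pairs is the
    model that produced the published force summaries.
    """
    if p1.metric != p2.metric:
        raise ValueError("summary points must share a metric")
    if p1.x == p2.x:
        raise ValueError("summary points have identical x: line undetermined")
    slope = (p2.F - p1.F) / (p2.x - p1.x)
    intercept = p1.F - slope * p1.x
    metric = p1.metric
    unit = Unit(metric_unit) if metric_unit is not None else CANONICAL_UNITS[metric]
    return LinearImpactModel(metric, slope, intercept, unit, "table_reconciled")


def recover_from_mean_sd(
    mean_point: SummaryPoint,
    slope_sign: int,
    metric_unit: Unit | str | None = None,
) -> LinearImpactModel:
    """Line recovered from a published mean +/- SD summary pair.

    For F = a*x + b, sd(F) = |a| * sd(x) exactly, so |a| is the ratio of
    the published SDs; the sign must be supplied (it is not identifiable
    from SDs) and the intercept follows from the means.
    """
    if mean_point.sd_pair is None:
        raise ValueError("mean_point must carry an sd_pair")
    if slope_sign not in (-1, 1):
        raise ValueError("slope_sign must be +1 or -1")
    x_sd, f_sd = mean_point.sd_pair
    if x_sd == 0:
        raise ValueError("metric SD of zero: slope undetermined")
    slope = slope_sign * f_sd / x_sd
    intercept = mean_point.F - slope * mean_point.x
    metric = mean_point.metric
    unit = Unit(metric_unit) if metric_unit is not None else CANONICAL_UNITS[metric]
    return LinearImpactModel(metric, slope, intercept, unit, "table_reconciled")


@dataclass(frozen=True)
class ImpactModelSet:
    """At most one impact-force model per metric, under a set id."""

    set_id: str
    models: Mapping[Metric, LinearImpactModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fixed: dict[Metric, LinearImpactModel] = {}
        for key, model in dict(self.models).items():
            metric = _as_metric(key)
            if metric != model.metric:
                raise ValueError(f"model filed under {metric.value!r} is for "
                                 f"{model.metric.value!r}")
            if metric in fixed:
                raise ValueError(f"duplicate model for metric {metric.value!r}")
            fixed[metric] = model
        if not fixed:
            raise ValueError("model set is empty")
        object.__setattr__(self, "models", fixed)

    @classmethod
    def from_models(
        cls, set_id: str, models: Sequence[LinearImpactModel]
    ) -> "ImpactModelSet":
        return cls(set_id, {m.metric: m for m in models})

    def per_metric_forces(
        self, metrics: Mapping[Metric | str, float]
    ) -> dict[Metric, float]:
        """Evaluate every available model on the supplied subject metrics.

        Subject metrics are given in canonical units (years, kg, m, mm);
        body mass is converted to newtons when a weight model expects N.
        """
        forces: dict[Metric, float] = {}
        supplied = {_as_metric(k): float(v) for k, v in metrics.items()
                    if v is not None and math.isfinite(float(v))}
        for metric in METRIC_ORDER:
            model = self.models.get(metric)
            if model is None or metric not in supplied:
                continue
            x = supplied[metric]
            if metric is Metric.WEIGHT and model.metric_unit is Unit.NEWTONS:
                x = x * GRAVITY
            forces[metric] = model.evaluate(x)
        return forces

    def max_impact_force(
        self, metrics: Mapping[Metric | str, float]
    ) -> tuple[float, Metric]:
        return max_impact_force(self, metrics)


def max_impact_force(
    model_set: ImpactModelSet, metrics: Mapping[Metric | str, float]
) -> tuple[float, Metric]:
    """Largest predicted impact force across available metrics.

    Returns the force (kN) and the metric that produced it; exact ties go
    to the earlier metric in the fixed order age < weight < height < stt.
    """
    forces = model_set.per_metric_forces(metrics)
    if not forces:
        raise ValueError("no metric has both a model and a subject value")
    best = max(METRIC_ORDER, key=lambda m: (forces.get(m, -math.inf)))
    # max() with key keeps the *last* of tied items; walk in order instead.
    best_force = max(forces.values())
    for metric in METRIC_ORDER:
        if metric in forces and forces[metric] == best_force:
            return best_force, metric
    return best_force, best  # pragma: no cover - unreachable


# ---------------------------------------------------------------------------
# Built-in coefficient sets
# ---------------------------------------------------------------------------

#: Published univariate equations, coefficients exactly as printed.
#: The weight equation takes weight in newtons.
_AS_PRINTED = (
    (Metric.AGE, -0.103, 10.2, Unit.YEARS),
    (Metric.WEIGHT, 0.00756, 0.00555, Unit.NEWTONS),
    (Metric.HEIGHT, 4.55, -2.72, Unit.M),
    (Metric.STT, -0.0723, 7.10, Unit.MM),
)

# Published control-group summary pairs used for table reconciliation:
# quartile (metric, force) pairs for age/weight/height and the mean +/- SD
# pair for STT.  Forces in kN; ages in years, weight in kg, height in m,
# STT in mm.
CONTROL_AGE_QUARTILES = (
    SummaryPoint(Metric.AGE, 54.0, 4.12, "quartile"),
    SummaryPoint(Metric.AGE, 68.8, 3.15, "quartile"),
)
CONTROL_WEIGHT_QUARTILES = (
    SummaryPoint(Metric.WEIGHT, 47.0, 3.87, "quartile"),
    SummaryPoint(Metric.WEIGHT, 60.1, 4.14, "quartile"),
)
CONTROL_HEIGHT_QUARTILES = (
    SummaryPoint(Metric.HEIGHT, 1.54, 4.21, "quartile"),
    SummaryPoint(Metric.HEIGHT, 1.65, 4.89, "quartile"),
)
CONTROL_STT_MEAN_SD = SummaryPoint(
    Metric.STT, 34.3, 4.42, "mean", sd_pair=(8.78, 0.692)
)


def as_printed() -> ImpactModelSet:
    """The published coefficient set, verbatim (weight in newtons)."""
    models = [
        LinearImpactModel(m, s, b, u, "as_printed") for m, s, b, u in _AS_PRINTED
    ]
    return ImpactModelSet.from_models("as_printed", models)


def table_reconciled() -> ImpactModelSet:
    """Models recovered from the published cohort summary tables.

    Age, weight and height lines pass exactly through the control group's
    quartile pairs; the STT line has slope -(force SD)/(STT SD) anchored
    at the control means.  The negative STT sign encodes soft-tissue
    attenuation of impact.  This set reproduces the published group-level
    force summaries and is internally consistent, unlike ``as_printed``.
    """
    models = [
        recover_from_two_points(*CONTROL_AGE_QUARTILES),
        recover_from_two_points(*CONTROL_WEIGHT_QUARTILES),
        recover_from_two_points(*CONTROL_HEIGHT_QUARTILES),
        recover_from_mean_sd(CONTROL_STT_MEAN_SD, slope_sign=-1),
    ]
    return ImpactModelSet.from_models("table_reconciled", models)


def builtin_model_set(name: str) -> ImpactModelSet:
    """Look up a built-in coefficient set by name."""
    builders = {"as_printed": as_printed, "table_reconciled": table_reconciled}
    try:
        return builders[name]()
    except KeyError:
        raise ValueError(
            f"unknown model set {name!r}; expected one of {sorted(builders)}"
        ) from None


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def model_set_to_json(model_set: ImpactModelSet, path: str | Path | None = None) -> dict:
    """Serialise a model set to the JSON interchange structure."""
    payload = {
        "set_id": model_set.set_id,
        "models": [model_set.models[m].to_dict()
                   for m in METRIC_ORDER if m in model_set.models],
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=2))
    return payload


def model_set_from_json(source: str | Path | Mapping) -> ImpactModelSet:
    if isinstance(source, Mapping):
        payload = source
    else:
        payload = json.loads(Path(source).read_text())
    models = [
        LinearImpactModel(
            d["metric"], float(d["slope"]), float(d["intercept"]),
            d["metric_unit"], d.get("provenance", "custom"),
        )
        for d in payload["models"]
    ]
    return ImpactModelSet.from_models(str(payload["set_id"]), models)


def load_literature_studies(
    models_csv: str | Path,
    points_csv: str | Path | None = None,
) -> list[LiteratureStudy]:
    """Read study records from CSV.

    ``models_csv`` columns: metric,label,n_samples[,slope,intercept[,metric_unit]]
    (slope/intercept blank when the study only contributes points).
    ``points_csv`` long-format columns: metric,label,x,F.
    """
    points: dict[tuple[str, str], list[tuple[float, float]]] = {}
    if points_csv is not None:
        with open(points_csv, newline="") as fh:
            for row in csv.DictReader(fh):
                key = (row["metric"].strip().lower(), row["label"].strip())
                points.setdefault(key, []).append((float(row["x"]), float(row["F"])))
    studies: list[LiteratureStudy] = []
    with open(models_csv, newline="") as fh:
        for row in csv.DictReader(fh):
            metric = _as_metric(row["metric"].strip())
            label = row["label"].strip()
            model = None
            if row.get("slope") not in (None, "",) and row.get("intercept") not in (None, ""):
                unit = row.get("metric_unit") or CANONICAL_UNITS[metric].value
                model = LinearImpactModel(
                    metric, float(row["slope"]), float(row["intercept"]),
                    unit, "as_printed",
                )
            pts = points.get((metric.value, label))
            studies.append(
                LiteratureStudy(
                    metric, label, int(row["n_samples"]),
                    tuple(pts) if pts else None, model,
                )
            )
    return studies


def aggregate_studies(
    studies: Sequence[LiteratureStudy],
    metric: Metric | str,
    weighted: bool = False,
) -> LinearImpactModel:
    """Aggregate one metric's studies into a single force model.

    Each study contributes its reported line (or an OLS fit to its points);
    lines are then averaged, optionally weighted by study sample size.
    """
    metric = _as_metric(metric)
    chosen = [s for s in studies if s.metric == metric]
    if not chosen:
        raise ValueError(f"no studies for metric {metric.value!r}")
    models = [s.as_model() for s in chosen]
    weights = [s.n_samples for s in chosen] if weighted else None
    return aggregate_models(models, weights)
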