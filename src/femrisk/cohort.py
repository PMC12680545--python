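"""Synthetic matched two-group cohorts.

Emulates a retrospective hip-fracture study: n fracture subjects, each
matched to a control within stated tolerances on age, height and weight,
with group-specific trochanteric soft-tissue thickness and a per-subject
femoral strength drawn from a bone-quality model calibrated to a
configured group effect on the Bone Strength Index.

Characteristic metrics are drawn from two-piece normal distributions
quantile-matched to published group summaries (median and quartiles can
be asymmetric), using stratified inverse-CDF sampling by default so that
a cohort of ten reproduces the summaries it is meant to emulate.  All
randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .impact import ImpactModelSet, builtin_model_set

__all__ = ["CohortSpec", "generate_cohort", "COHORT_COLUMNS"]

COHORT_COLUMNS = ["id", "group", "age_years", "weight_kg", "height_m",
                  "stt_mm", "strength_kN"]

_Z75 = float(norm.ppf(0.75))  # 0.6745: quartile z of the standard normal


@dataclass(frozen=True)
class CohortSpec:
    """Distributional description of the matched cohort.

    ``*_mqq`` entries are (median, lower quartile, upper quartile) of the
    control group; fracture metrics follow from the per-pair matching
    offsets.  STT is not matched and is drawn per group from (mean, SD),
    floored at ``stt_floor``.  The bone-quality proxy is drawn per subject
    around ``bsi_control_mean`` (shifted by ``bsi_effect`` in the fracture
    group, SD ``bsi_sd``) and multiplied by the subject's maximum impact
    force to give strength, so the expected group difference in BSI equals
    the configured effect.
    """

    n_per_group: int = 10
    age_mqq: tuple[float, float, float] = (64.0, 54.0, 68.8)
    weight_mqq: tuple[float, float, float] = (52.4, 47.0, 60.1)
    height_mqq: tuple[float, float, float] = (1.60, 1.54, 1.65)
    stt_control: tuple[float, float] = (34.3, 8.78)
    stt_fracture: tuple[float, float] = (22.6, 7.10)
    stt_floor: float = 2.0
    bsi_control_mean: float = 0.862
    bsi_effect: float = -0.326
    bsi_sd: float = 0.336
    bsi_floor: float = 0.05
    # Per-pair matching offsets (fracture minus control), uniform ranges.
    age_offset: tuple[float, float] = (-0.3, 0.0)
    height_offset: tuple[float, float] = (0.02, 0.04)
    weight_offset: tuple[float, float] = (1.6, 6.0)
    match_tol: tuple[float, float, float] = (0.3, 0.04, 6.0)
    stratified: bool = True
    model_set: str = "table_reconciled"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        for name in ("age_mqq", "weight_mqq", "height_mqq"):
            m, q1, q3 = getattr(self, name)
            if not q1 < m < q3:
                raise ValueError(f"{name} must satisfy q1 < median < q3")
        for name in ("stt_control", "stt_fracture"):
            if getattr(self, name)[1] <= 0:
                raise ValueError(f"{name} SD must be positive")
        if self.bsi_sd <= 0:
            raise ValueError("bsi_sd must be positive")
        tol = self.match_tol
        for rng_, t, name in ((self.age_offset, tol[0], "age"),
                              (self.height_offset, tol[1], "height"),
                              (self.weight_offset, tol[2], "weight")):
            lo, hi = rng_
            if lo > hi:
                raise ValueError(f"{name}_offset range is inverted")
            if max(abs(lo), abs(hi)) > t + 1e-12:
                raise ValueError(
                    f"{name}_offset exceeds the matching tolerance +/-{t}; "
                    "matching is infeasible")

    def with_(self, **kwargs) -> "CohortSpec":
        return replace(self, **kwargs)


def _std_normal_sample(rng: np.random.Generator, n: int,
                       stratified: bool) -> np.ndarray:
    """Standard-normal draws, optionally via jittered stratified inversion."""
    if not stratified:
        return rng.standard_normal(n)
    p = (rng.permutation(n) + rng.uniform(0.0, 1.0, n)) / n
    return norm.ppf(np.clip(p, 1e-9, 1 - 1e-9))


def _two_piece(u: np.ndarray, mqq: tuple[float, float, float]) -> np.ndarray:
    """Map standard-normal draws through a two-piece normal matched to a
    (median, q1, q3) summary; exact at the three quantiles."""
    m, q1, q3 = mqq
    upper = (q3 - m) / _Z75
    lower = (m - q1) / _Z75
    return m + np.where(u >= 0, u * upper, u * lower)


def generate_cohort(spec: CohortSpec | None = None,
                    model_set: ImpactModelSet | None = None) -> pd.DataFrame:
    """Generate the matched cohort table.

    Returns a DataFrame with columns id, group, age_years, weight_kg,
    height_m, stt_mm, strength_kN; one matched fracture/control pair per
    row index pair (C01/F01, ...).  Deterministic given the spec.
    """
    spec = spec or CohortSpec()
    models = model_set or builtin_model_set(spec.model_set)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_group

    age_c = _two_piece(_std_normal_sample(rng, n, spec.stratified), spec.age_mqq)
    weight_c = _two_piece(_std_normal_sample(rng, n, spec.stratified),
                          spec.weight_mqq)
    height_c = _two_piece(_std_normal_sample(rng, n, spec.stratified),
                          spec.height_mqq)
    age_c = np.clip(age_c, 50.0, 90.0)          # study eligibility window
    weight_c = np.clip(weight_c, 30.0, 120.0)
    height_c = np.clip(height_c, 1.30, 1.95)

    age_f = age_c + rng.uniform(*spec.age_offset, n)
    height_f = height_c + rng.uniform(*spec.height_offset, n)
    weight_f = weight_c + rng.uniform(*spec.weight_offset, n)

    stt_c = np.maximum(spec.stt_control[0] + spec.stt_control[1]
                       * _std_normal_sample(rng, n, spec.stratified),
                       spec.stt_floor)
    stt_f = np.maximum(spec.stt_fracture[0] + spec.stt_fracture[1]
                       * _std_normal_sample(rng, n, spec.stratified),
                       spec.stt_floor)

    quality_c = np.maximum(spec.bsi_control_mean + spec.bsi_sd
                           * _std_normal_sample(rng, n, spec.stratified),
                           spec.bsi_floor)
    quality_f = np.maximum(spec.bsi_control_mean + spec.bsi_effect
                           + spec.bsi_sd
                           * _std_normal_sample(rng, n, spec.stratified),
                           spec.bsi_floor)

    rows = []
    for grp, tag, age, weight, height, stt, quality in (
        ("control", "C", age_c, weight_c, height_c, stt_c, quality_c),
        ("fracture", "F", age_f, weight_f, height_f, stt_f, quality_f),
    ):
        for i in range(n):
            metrics = {"age": age[i], "weight": weight[i],
                       "height": height[i], "stt": stt[i]}
            force, _ = models.max_impact_force(metrics)
            rows.append({
                "id": f"{tag}{i + 1:02d}",
                "group": grp,
                "age_years": float(age[i]),
                "weight_kg": float(weight[i]),
                "height_m": float(height[i]),
                "stt_mm": float(stt[i]),
                "strength_kN": float(quality[i] * force),
            })
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
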