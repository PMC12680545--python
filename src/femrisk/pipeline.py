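"""End-to-end orchestration: configuration, staging and the full pipeline.

Two modes:

``cohort``
    Statistical mode — generate (or load) a matched cohort table with
    per-subject strengths, evaluate impact forces and BSI, and run the
    group comparisons.

``imaging``
    Physics mode — for each configured subject, obtain a grayscale
    volume + segmentation (from files or the phantom generator), map BVF,
    mesh, run the sideways-fall FE simulation for strength, measure STT
    from the masks, then combine with the subject's metrics into the BSI.

Stages log their resolved parameters; outputs are written atomically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .bsi import evaluate_cohort, metric_attribution
from .bvf import BVFMap, compute_bvf
from .cohort import CohortSpec, generate_cohort
from .fe import (MaterialLaw, SidewaysFallSetup, StrengthResult, build_mesh,
                 solve_nonlinear)
from .fe.mesh import nodes_in_voxel_mask, surface_patch_nodes
from .impact import ImpactModelSet, builtin_model_set, model_set_from_json
from .phantom import Phantom, PhantomSpec, generate_phantom
from .stats import CohortComparison, compare_many
from .stt import measure_stt

__all__ = ["SolverParams", "RunConfig", "PipelineResult", "run_pipeline",
           "phantom_strength", "resolve_model_set", "load_config"]

log = logging.getLogger(__name__)

DEFAULT_MEASURES = ["bsi", "strength_kN", "max_force_kN", "age_years",
                    "weight_kg", "height_m", "stt_mm"]


@dataclass(frozen=True)
class SolverParams:
    """FE solver controls: load stepping and iteration tolerances."""

    target_strain: float = 0.03
    n_steps: int = 30
    cg_rtol: float = 1e-6
    picard_tol: float = 0.01
    picard_maxiter: int = 25
    cutoff: float = 0.01

    def __post_init__(self) -> None:
        if self.n_steps < 5:
            raise ValueError("solver.n_steps must be >= 5")
        if not 0 < self.target_strain < 0.2:
            raise ValueError("solver.target_strain must lie in (0, 0.2)")
        if not 0 <= self.cutoff < 1:
            raise ValueError("solver.cutoff must lie in [0, 1)")


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration for `run_pipeline`."""

    mode: str = "cohort"                    # "cohort" | "imaging"
    seed: int = 0
    model_set: str = "table_reconciled"     # name or path to JSON
    alpha: float = 0.05
    alternative: str = "two-sided"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    cohort_csv: str | None = None           # load instead of generating
    subjects: tuple[dict, ...] = ()         # imaging mode
    material: MaterialLaw = field(default_factory=MaterialLaw)
    solver: SolverParams = field(default_factory=SolverParams)
    bvf_window_radius: int = 10
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("cohort", "imaging"):
            raise ValueError("mode must be 'cohort' or 'imaging'")
        if self.mode == "imaging" and not self.subjects:
            raise ValueError("imaging mode needs at least one subject")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a JSON run configuration.

    Unknown keys are rejected so that typos cannot silently fall back to
    defaults.
    """
    raw = json.loads(Path(path).read_text())
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    def build(cls, payload, name):
        if payload is None:
            return cls()
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - fields
        if unknown:
            raise ValueError(f"unknown {name} keys: {sorted(unknown)}")
        return cls(**payload)

    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    kwargs["cohort"] = build(CohortSpec, raw.get("cohort"), "cohort")
    kwargs["material"] = build(MaterialLaw, raw.get("material"), "material")
    kwargs["solver"] = build(SolverParams, raw.get("solver"), "solver")
    if "subjects" in kwargs and kwargs["subjects"] is not None:
        kwargs["subjects"] = tuple(kwargs["subjects"])
    return RunConfig(**kwargs)


def resolve_model_set(name_or_path: str) -> ImpactModelSet:
    if name_or_path in ("as_printed", "table_reconciled"):
        return builtin_model_set(name_or_path)
    return model_set_from_json(name_or_path)


@dataclass
class PipelineResult:
    results: pd.DataFrame
    comparisons: list[CohortComparison]
    attribution: pd.DataFrame
    meta: dict


def phantom_strength(phantom: Phantom,
                     material: MaterialLaw | None = None,
                     solver: SolverParams | None = None,
                     bvf_map: BVFMap | None = None,
                     bvf_window_radius: int = 10) -> tuple[StrengthResult, BVFMap]:
    """BVF-map, mesh and solve one phantom; returns (strength, BVF map).

    ``bvf_map`` short-circuits the mapping stage (e.g. to use the ground
    truth, or a weakened copy of it).
    """
    material = material or MaterialLaw()
    solver = solver or SolverParams()
    if bvf_map is None:
        bvf_map = compute_bvf(phantom.volume, phantom.mask,
                              window_radius=bvf_window_radius)
    mesh = build_mesh(bvf_map, cutoff=solver.cutoff)
    head = surface_patch_nodes(mesh, phantom.head_voxels)
    troch = surface_patch_nodes(mesh, phantom.trochanter_voxels)
    distal = nodes_in_voxel_mask(mesh, phantom.distal_voxels)
    setup = SidewaysFallSetup(
        head_nodes=head, trochanter_nodes=troch, distal_nodes=distal,
        diaphysis_tilt=phantom.spec.diaphysis_tilt,
        internal_rotation=phantom.spec.internal_rotation,
    )
    result = solve_nonlinear(
        mesh, setup, law=material,
        target_strain=solver.target_strain, n_steps=solver.n_steps,
        cg_rtol=solver.cg_rtol, picard_tol=solver.picard_tol,
        picard_maxiter=solver.picard_maxiter,
    )
    return result, bvf_map


def _imaging_subject_row(sub: dict, config: RunConfig) -> dict:
    """Run the physics chain for one imaging-mode subject description."""
    sid = str(sub.get("id", "S"))
    group = str(sub.get("group", "control"))
    if "phantom" in sub or ("volume" not in sub):
        overrides = dict(sub.get("phantom") or {})
        overrides.setdefault("seed", config.seed)
        phantom = generate_phantom(PhantomSpec(**overrides))
        volume, mask = phantom.volume, phantom.mask
    else:
        phantom = None
        volume = fio.read_volume(sub["volume"])
        mask = fio.read_mask(sub["mask"])
    log.info("[%s] BVF mapping", sid)
    bvf_map = compute_bvf(volume, mask, window_radius=config.bvf_window_radius)
    stt = measure_stt(mask.bone, mask.body, mask.voxel_dims)
    if phantom is not None:
        strength, _ = phantom_strength(phantom, config.material,
                                       config.solver, bvf_map=bvf_map)
    else:
        raise ValueError(
            f"subject {sid!r}: file-based FE runs need patch definitions; "
            "supply a phantom spec instead or use the library API directly")
    return {
        "id": sid, "group": group,
        "age_years": float(sub["age_years"]),
        "weight_kg": float(sub["weight_kg"]),
        "height_m": float(sub["height_m"]),
        "stt_mm": stt.stt_mm,
        "strength_kN": strength.strength_kN,
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the configured pipeline and (optionally) write its outputs."""
    models = resolve_model_set(config.model_set)
    log.info("pipeline mode=%s seed=%d model_set=%s",
             config.mode, config.seed, models.set_id)

    if config.mode == "cohort":
        if config.cohort_csv:
            cohort = fio.read_cohort_csv(config.cohort_csv)
        else:
            spec = config.cohort.with_(seed=config.seed)
            cohort = generate_cohort(spec, model_set=models)
    else:
        rows = [_imaging_subject_row(dict(sub), config)
                for sub in config.subjects]
        cohort = pd.DataFrame(rows)

    results = evaluate_cohort(cohort, models)
    attribution = metric_attribution(results)

    comparisons: list[CohortComparison] = []
    counts = results["group"].value_counts()
    if counts.get("fracture", 0) >= 2 and counts.get("control", 0) >= 2:
        comparisons = compare_many(results, DEFAULT_MEASURES,
                                   alpha=config.alpha,
                                   alternative=config.alternative)

    meta = {
        "mode": config.mode, "seed": config.seed,
        "model_set": models.set_id,
        "n_subjects": int(len(results)),
        "alternative": config.alternative,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        fio.write_csv_atomic(results, out / "results.csv")
        fio.write_csv_atomic(attribution, out / "attribution.csv")
        fio.write_json_atomic([c.to_dict() for c in comparisons],
                              out / "comparisons.json")
        fio.write_json_atomic(meta | {"config": _config_dict(config)},
                              out / "run_meta.json")
    return PipelineResult(results=results, comparisons=comparisons,
                          attribution=attribution, meta=meta)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["subjects"] = list(d.get("subjects") or ())
    return d
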