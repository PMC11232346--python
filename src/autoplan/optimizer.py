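"""Fluence optimization and prescription normalization.

Projected-gradient descent on nonnegative beamlet weights with Armijo-style
backtracking.  The schedule runs in rounds (default two rounds of 100
iterations); the step-size schedule restarts at each round boundary,
emulating a warm restart of the optimizer, and with a stopping tolerance of
zero every iteration is executed.  DVH objective voxel subsets are
re-identified at every objective evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .aux_structures import AuxStructureSet
from .dose import DoseGrid, InfluenceModel, resample_mask_to_grid
from .grid import RoiMask
from .objectives import ObjectiveTemplate, term_value_and_gradient
from .phantom import PlanCase, Prescription

__all__ = [
    "OptimizerConfig",
    "Plan",
    "DivergenceError",
    "optimize_plan",
    "normalize_to_coverage",
]

log = logging.getLogger(__name__)

#: delivery metadata carried on every plan, informational only
MACHINE_METADATA = {"pitch": 0.43, "jaw_width_cm": 2.51, "delivery_time_factor": 1.7}


class DivergenceError(RuntimeError):
    """Objective increased persistently despite backtracking."""


@dataclass(frozen=True)
class OptimizerConfig:
    rounds: int = 2
    iterations_per_round: int = 100
    stopping_tolerance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1 or self.iterations_per_round < 1:
            raise ValueError("rounds and iterations_per_round must be >= 1")


@dataclass
class Plan:
    """An optimized (and possibly normalized) plan."""

    weights: np.ndarray
    dose: DoseGrid
    template: ObjectiveTemplate
    normalization_scale: float
    objective_history: list[float]
    machine_metadata: dict = field(default_factory=lambda: dict(MACHINE_METADATA))


class _RoiDose:
    """Flat dose-grid index set for one ROI, with cached scatter support."""

    def __init__(self, mask: RoiMask, dose_grid) -> None:
        sel = resample_mask_to_grid(mask, dose_grid)
        self.flat_idx = np.flatnonzero(sel.reshape(-1))

    @property
    def empty(self) -> bool:
        return self.flat_idx.size == 0


def _objective_on_weights(w, model, terms, t_ref):
    """Objective value and gradient w.r.t. weights at w."""
    dose_flat = model.dose_values(w).reshape(-1)
    total = 0.0
    grad_flat = np.zeros_like(dose_flat)
    for spec, roi in terms:
        v, g = term_value_and_gradient(spec, dose_flat[roi.flat_idx], t_ref)
        total += v
        np.add.at(grad_flat, roi.flat_idx, g)
    grad_w = model.backproject(grad_flat.reshape(model.dose_grid.shape))
    return total, grad_w


def _objective_value(w, model, terms, t_ref):
    dose_flat = model.dose_values(w).reshape(-1)
    total = 0.0
    for spec, roi in terms:
        v, _ = term_value_and_gradient(spec, dose_flat[roi.flat_idx], t_ref)
        total += v
    return total


def optimize_plan(case: PlanCase, aux: AuxStructureSet, model: InfluenceModel,
                  template: ObjectiveTemplate,
                  cfg: OptimizerConfig = OptimizerConfig()) -> Plan:
    """Run the multi-round projected-gradient optimization.

    Deterministic given the inputs (the seed is carried for config stability;
    no stochastic elements are enabled).  The returned plan is *not* yet
    normalized; apply :func:`normalize_to_coverage` afterwards.
    """
    structures = {**case.structures, **aux.masks}
    terms = []
    for spec in template:
        if spec.roi_name not in structures:
            raise KeyError(f"objective references unknown ROI {spec.roi_name!r}")
        roi = _RoiDose(structures[spec.roi_name], model.dose_grid)
        if roi.empty:
            log.info("objective ROI %r is empty on the dose grid; term skipped",
                     spec.roi_name)
            continue
        terms.append((spec, roi))
    t_ref = template.prescription.total_dose_gy

    # start from uniform weights scaled so the mean PTV dose ~= prescription
    ptv = _RoiDose(case["PTV"], model.dose_grid)
    w = np.ones(model.n_beamlets)
    mean_ptv = float(model.dose_values(w).reshape(-1)[ptv.flat_idx].mean())
    if mean_ptv <= 0:
        raise RuntimeError("uniform beams deposit no dose in the PTV")
    w *= t_ref / mean_ptv

    f, g = _objective_on_weights(w, model, terms, t_ref)
    history = [f]
    gnorm2 = float(g @ g)
    t0 = f / gnorm2 if gnorm2 > 0 else 1.0
    n_bad = 0
    for rnd in range(cfg.rounds):
        t = t0  # step-size schedule restarts each round
        for _ in range(cfg.iterations_per_round):
            accepted = False
            for _bt in range(40):
                w_new = np.maximum(w - t * g, 0.0)
                if not np.any(w_new != w):
                    break
                f_new = _objective_value(w_new, model, terms, t_ref)
                if f_new <= f * (1 + 1e-12):
                    accepted = True
                    break
                t *= 0.5
            if accepted:
                prev = f
                w = w_new
                f, g = _objective_on_weights(w, model, terms, t_ref)
                if f > prev * (1 + 1e-9) + 1e-15:  # pragma: no cover - diagnostic
                    n_bad += 1
                    if n_bad > 5:
                        raise DivergenceError(
                            f"objective increased persistently (f={f:.4g})")
                else:
                    n_bad = 0
                t *= 1.4
            history.append(f)
            if cfg.stopping_tolerance > 0 and len(history) > 1 \
                    and history[-2] - history[-1] <= cfg.stopping_tolerance:
                break
        log.info("round %d done: objective %.6g", rnd + 1, f)

    dose = DoseGrid(grid=model.dose_grid, values=model.dose_values(w))
    return Plan(weights=w, dose=dose, template=template,
                normalization_scale=1.0, objective_history=history)


def dose_at_volume_pct(dose_values: np.ndarray, volume_pct: float) -> float:
    """Dose D such that volume_pct % of the voxels receive >= D
    (linear interpolation)."""
    return float(np.percentile(np.asarray(dose_values, float), 100.0 - volume_pct))


def normalize_to_coverage(dose: DoseGrid, ptv: RoiMask, presc: Prescription,
                          coverage_pct: float = 95.0) -> tuple[DoseGrid, float]:
    """Scale the dose so the prescription isodose covers ``coverage_pct`` %
    of the PTV: scale = prescription / D_coverage(PTV)."""
    sel = resample_mask_to_grid(ptv, dose.grid) if ptv.grid != dose.grid \
        else ptv.voxels
    vals = dose.values[sel]
    if vals.size == 0:
        raise ValueError("PTV is empty on the dose grid")
    d_cov = dose_at_volume_pct(vals, coverage_pct)
    if d_cov <= 0:
        raise ValueError("PTV dose is zero; cannot normalize")
    scale = presc.total_dose_gy / d_cov
    return DoseGrid(grid=dose.grid, values=dose.values * scale), scale
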