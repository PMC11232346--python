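"""Optimization objectives: the five penalty types (Max/Min Dose, Max/Min
DVH, Max EUD), the built-in 25-row objective template, and the generalized
equivalent uniform dose.

Penalty forms follow standard inverse-planning practice: one-sided quadratic
penalties, with DVH objectives restricted to the excess-volume voxels that
are cheapest to move (those between the dose threshold and the current dose
at the allowed volume, inclusive).  Every term is normalized by the squared prescription
dose so the template's printed weights (1e8-1e9 for targets and rings,
0.01-5 for mean-dose EUD terms) are usable as printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .aux_structures import AuxStructureSet
from .grid import RoiMask
from .phantom import Prescription

__all__ = [
    "ObjectiveKind",
    "ObjectiveSpec",
    "ObjectiveTemplate",
    "default_template",
    "geud",
    "geud_gradient",
    "objective_term",
    "term_value_and_gradient",
    "total_objective",
]


class ObjectiveKind(str, Enum):
    MAX_DOSE = "MaxDose"
    MIN_DOSE = "MinDose"
    MAX_DVH = "MaxDVH"
    MIN_DVH = "MinDVH"
    MAX_EUD = "MaxEUD"


DVH_KINDS = (ObjectiveKind.MAX_DVH, ObjectiveKind.MIN_DVH)


@dataclass(frozen=True)
class ObjectiveSpec:
    """One row of an objective template."""

    roi_name: str
    kind: ObjectiveKind
    target_gy: float
    weight: float
    volume_pct: float | None = None   # DVH kinds only
    eud_a: float | None = None        # MaxEUD only

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ObjectiveKind(self.kind))
        if self.target_gy < 0:
            raise ValueError(f"{self.roi_name}: target dose must be >= 0")
        if self.weight <= 0:
            raise ValueError(f"{self.roi_name}: weight must be positive")
        if self.kind in DVH_KINDS:
            if self.volume_pct is None or not (0 <= self.volume_pct <= 100):
                raise ValueError(
                    f"{self.roi_name}: DVH objective needs volume_pct in [0, 100]")
        if self.kind is ObjectiveKind.MAX_EUD:
            if self.eud_a is None or self.eud_a == 0:
                raise ValueError(f"{self.roi_name}: MaxEUD needs a nonzero eud_a")


@dataclass
class ObjectiveTemplate:
    """Ordered objective list plus the prescription it was written for."""

    specs: list[ObjectiveSpec]
    prescription: Prescription

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    def roi_names(self) -> list[str]:
        return sorted({s.roi_name for s in self.specs})


def default_template(aux: AuxStructureSet,
                     prescription: Prescription = Prescription()) -> ObjectiveTemplate:
    """The built-in 25-row objective template.

    Targets, volumes, weights and EUD exponents are the planning template the
    pipeline is built around; the bowel-helper ``bag`` row's volume parameter
    is per-patient, floor(100*195/V_bag) %, and the row is omitted when the
    helper structure is empty.
    """
    K = ObjectiveKind
    rows: list[ObjectiveSpec] = [
        ObjectiveSpec("PTV_new", K.MAX_DOSE, 52.4, 1e9),
        ObjectiveSpec("PTV_new", K.MIN_DVH, 51.0, 5e9, volume_pct=97.0),
        ObjectiveSpec("PTV_new", K.MIN_DVH, 50.4, 5e9, volume_pct=98.0),
        ObjectiveSpec("PTV", K.MAX_EUD, 52.0, 1.5e9, eud_a=150.0),
        ObjectiveSpec("PTV_new-3mm", K.MIN_DOSE, 51.0, 8e9),
        ObjectiveSpec("ring0.5", K.MAX_DOSE, 50.4, 3e8),
        ObjectiveSpec("ring1", K.MAX_DOSE, 45.0, 3e8),
        ObjectiveSpec("ring2", K.MAX_DOSE, 38.0, 3e8),
        ObjectiveSpec("ring3", K.MAX_DOSE, 28.0, 3e8),
        ObjectiveSpec("nt", K.MAX_DOSE, 20.0, 3e8),
        ObjectiveSpec("ring1", K.MAX_EUD, 0.0, 0.01, eud_a=1.0),
        ObjectiveSpec("ring2", K.MAX_EUD, 0.0, 0.01, eud_a=1.0),
        ObjectiveSpec("ring3", K.MAX_EUD, 0.0, 0.01, eud_a=1.0),
        ObjectiveSpec("nt", K.MAX_EUD, 0.0, 0.3, eud_a=1.0),
    ]
    if aux.bag_volume_pct is not None:
        rows.append(ObjectiveSpec("bag", K.MAX_DVH, 42.0, 3e9,
                                  volume_pct=float(aux.bag_volume_pct)))
    rows += [
        ObjectiveSpec("bladder", K.MAX_DVH, 38.0, 2e9, volume_pct=60.0),
        ObjectiveSpec("rectum", K.MAX_DVH, 38.0, 2e9, volume_pct=60.0),
        ObjectiveSpec("bowel bag_PTV", K.MIN_DOSE, 40.0, 2e9),
        ObjectiveSpec("bladder-ptv", K.MAX_EUD, 0.0, 1.0, eud_a=1.0),
        ObjectiveSpec("rectum-ptv", K.MAX_EUD, 0.0, 0.8, eud_a=1.0),
        ObjectiveSpec("bowel bag-ptv", K.MAX_EUD, 0.0, 5.0, eud_a=1.0),
        ObjectiveSpec("femoral head_L", K.MAX_EUD, 0.0, 0.5, eud_a=1.0),
        ObjectiveSpec("femoral head_R", K.MAX_EUD, 0.0, 0.5, eud_a=1.0),
        ObjectiveSpec("kidney_L", K.MAX_EUD, 0.0, 1.0, eud_a=1.0),
        ObjectiveSpec("kidney_R", K.MAX_EUD, 0.0, 1.0, eud_a=1.0),
    ]
    return ObjectiveTemplate(specs=rows, prescription=prescription)


# ---------------------------------------------------------------------------
# gEUD
# ---------------------------------------------------------------------------

def geud(dose_values: np.ndarray, a: float) -> float:
    """Generalized equivalent uniform dose: the power mean (mean(d^a))^(1/a).

    a = 1 gives the mean dose; large positive a approaches the maximum.
    Computed in a scaled form that is stable for large exponents.
    """
    d = np.asarray(dose_values, dtype=np.float64)
    if d.size == 0:
        raise ValueError("gEUD of an empty ROI is undefined")
    if a == 0:
        raise ValueError("gEUD exponent a must be nonzero")
    dmax = float(d.max())
    if dmax <= 0:
        return 0.0
    if a < 0 and float(d.min()) <= 0:
        return 0.0  # limit of the power mean with a zero present
    return dmax * float(np.mean((d / dmax) ** a)) ** (1.0 / a)


def geud_gradient(dose_values: np.ndarray, a: float) -> np.ndarray:
    """d(gEUD)/d(d_i) = (d_i / gEUD)^(a-1) / N, evaluated stably."""
    d = np.asarray(dose_values, dtype=np.float64)
    g = geud(d, a)
    n = d.size
    if g <= 0:
        return np.zeros(n)
    if a == 1.0:
        return np.full(n, 1.0 / n)
    with np.errstate(divide="ignore"):
        ratio = np.clip(d / g, 0.0, None)
        grad = np.where(ratio > 0, ratio ** (a - 1.0), 0.0)
    grad = np.where(np.isfinite(grad), grad, 0.0)
    return grad / n


# ---------------------------------------------------------------------------
# penalty terms
# ---------------------------------------------------------------------------

def _dose_at_volume(d: np.ndarray, volume_pct: float) -> float:
    """Current dose at the given cumulative volume (the dose D such that
    volume_pct % of the ROI receives >= D)."""
    return float(np.percentile(d, 100.0 - volume_pct))


def term_value_and_gradient(spec: ObjectiveSpec, roi_dose: np.ndarray,
                            t_ref_gy: float,
                            frozen_dvh_dose: float | None = None
                            ) -> tuple[float, np.ndarray]:
    """Penalty value and gradient w.r.t. the ROI's voxel doses.

    ``frozen_dvh_dose`` fixes the DVH volume-selection dose (used by
    finite-difference gradient checks; during optimization the selection is
    re-identified at every evaluation).
    """
    d = np.asarray(roi_dose, dtype=np.float64)
    n = d.size
    if n == 0:
        return 0.0, np.zeros(0)
    w = spec.weight
    t = spec.target_gy
    norm = t_ref_gy ** 2
    grad = np.zeros(n)
    kind = spec.kind

    if kind is ObjectiveKind.MAX_DOSE:
        excess = np.maximum(d - t, 0.0)
        value = w * float(np.mean(excess ** 2)) / norm
        grad = w * 2.0 * excess / (n * norm)
    elif kind is ObjectiveKind.MIN_DOSE:
        deficit = np.maximum(t - d, 0.0)
        value = w * float(np.mean(deficit ** 2)) / norm
        grad = -w * 2.0 * deficit / (n * norm)
    elif kind is ObjectiveKind.MAX_DVH:
        dv = frozen_dvh_dose if frozen_dvh_dose is not None \
            else _dose_at_volume(d, spec.volume_pct)
        sel = (d > t) & (d <= dv)
        excess = np.where(sel, d - t, 0.0)
        value = w * float(np.sum(excess ** 2)) / (n * norm)
        grad = w * 2.0 * excess / (n * norm)
    elif kind is ObjectiveKind.MIN_DVH:
        dv = frozen_dvh_dose if frozen_dvh_dose is not None \
            else _dose_at_volume(d, spec.volume_pct)
        sel = (d < t) & (d >= dv)
        deficit = np.where(sel, t - d, 0.0)
        value = w * float(np.sum(deficit ** 2)) / (n * norm)
        grad = -w * 2.0 * deficit / (n * norm)
    elif kind is ObjectiveKind.MAX_EUD:
        g = geud(d, spec.eud_a)
        excess = max(g - t, 0.0)
        value = w * excess ** 2 / norm
        if excess > 0:
            grad = w * 2.0 * excess / norm * geud_gradient(d, spec.eud_a)
    else:  # pragma: no cover
        raise ValueError(f"unknown objective kind {kind}")
    return float(value), grad


def objective_term(spec: ObjectiveSpec, dose: "DoseGrid", mask: RoiMask,
                   t_ref_gy: float,
                   frozen_dvh_dose: float | None = None
                   ) -> tuple[float, np.ndarray]:
    """Term value and gradient w.r.t. voxel doses, on the dose grid.

    The mask is resampled to the dose grid by voxel-center containment.
    An empty (resampled) mask contributes value 0 with a zero gradient.
    """
    from .dose import resample_mask_to_grid

    sel = resample_mask_to_grid(mask, dose.grid) if mask.grid != dose.grid \
        else mask.voxels
    grad3 = np.zeros(dose.grid.shape)
    idx = np.nonzero(sel)
    if idx[0].size == 0:
        return 0.0, grad3
    value, grad = term_value_and_gradient(spec, dose.values[idx], t_ref_gy,
                                          frozen_dvh_dose=frozen_dvh_dose)
    grad3[idx] = grad
    return value, grad3


def total_objective(template: ObjectiveTemplate, dose: "DoseGrid",
                    structures: dict[str, RoiMask]) -> tuple[float, np.ndarray]:
    """Weighted-sum objective over all template rows; gradient w.r.t. voxel
    doses on the dose grid."""
    total = 0.0
    grad = np.zeros(dose.grid.shape)
    t_ref = template.prescription.total_dose_gy
    for spec in template:
        if spec.roi_name not in structures:
            raise KeyError(f"objective references unknown ROI {spec.roi_name!r}")
        v, g = objective_term(spec, dose, structures[spec.roi_name], t_ref)
        total += v
        grad += g
    return total, grad
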