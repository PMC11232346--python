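"""Plan evaluation: cumulative DVHs, dose-volume queries, homogeneity /
conformity / gradient indices, and protocol constraint checking.

DVH convention: cumulative "volume receiving >= dose", with linear
interpolation between 0.05 Gy bins.  D_x% is the interpolated inverse of the
curve; V_xGy reads the curve at x Gy; D_cc queries convert the absolute
volume to a percentage of the ROI volume (used for the near-maximum
D_0.03cc).  The indices are

    HI   = (D_2% - D_98%) / D_50%                       (0 = perfectly uniform)
    CI   = TV_PTV^2 / (V_PTV * V_TVP)                   (1 = perfectly conformal)
    GI_x = V_x / V_TVP                                  (smaller = faster fall-off)

where TV_PTV is the PTV volume covered by the prescription isodose, V_TVP
the total prescription-isodose volume and V_x the x Gy isodose volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dose import DoseGrid, resample_mask_to_grid
from .grid import RoiMask
from .phantom import PlanCase, Prescription

__all__ = [
    "DvhCurve",
    "IsodoseVolumes",
    "ConstraintVerdict",
    "PlanMetrics",
    "cumulative_dvh",
    "dvh_query",
    "homogeneity_index",
    "conformity_index",
    "gradient_index",
    "isodose_volumes",
    "evaluate_plan",
    "PROTOCOL_ROWS",
]

DEFAULT_BIN_GY = 0.05
GRADIENT_THRESHOLDS_GY = (40.0, 30.0, 20.0, 10.0)


def _roi_dose_values(dose: DoseGrid, mask: RoiMask) -> np.ndarray:
    sel = resample_mask_to_grid(mask, dose.grid) if mask.grid != dose.grid \
        else mask.voxels
    return dose.values[sel]


@dataclass
class DvhCurve:
    """Cumulative DVH: percent of ROI volume receiving at least each bin dose."""

    roi_name: str
    dose_bins_gy: np.ndarray
    cumulative_volume_pct: np.ndarray
    roi_volume_cc: float

    def v_at(self, dose_gy: float) -> float:
        """Volume percentage receiving >= dose_gy (linear interpolation)."""
        return float(np.interp(dose_gy, self.dose_bins_gy,
                               self.cumulative_volume_pct))

    def d_at(self, volume_pct: float) -> float:
        """Smallest dose received by at least volume_pct % of the ROI
        (interpolated inverse of the nonincreasing curve)."""
        v = self.cumulative_volume_pct
        b = self.dose_bins_gy
        if volume_pct >= v[0]:
            return float(b[0])
        if volume_pct <= v[-1]:
            return float(b[-1])
        # v is nonincreasing: interpolate on the reversed curve
        return float(np.interp(volume_pct, v[::-1], b[::-1]))

    def d_cc(self, volume_cc: float) -> float:
        """Dose to the hottest ``volume_cc`` of the ROI (e.g. D_0.03cc)."""
        if volume_cc > self.roi_volume_cc:
            raise ValueError(
                f"queried volume {volume_cc} cc exceeds ROI volume "
                f"{self.roi_volume_cc:.2f} cc")
        return self.d_at(100.0 * volume_cc / self.roi_volume_cc)


def cumulative_dvh(dose: DoseGrid, mask: RoiMask,
                   bin_gy: float = DEFAULT_BIN_GY) -> DvhCurve:
    """Cumulative DVH of a structure on the dose grid."""
    vals = _roi_dose_values(dose, mask)
    if vals.size == 0:
        raise ValueError(f"mask {mask.name!r} is empty on the dose grid")
    dmax = float(vals.max())
    bins = np.arange(0.0, dmax + 2 * bin_gy, bin_gy)
    sorted_vals = np.sort(vals)
    # count of voxels with dose >= b (1e-9 guard against bin-edge float drift)
    n_ge = vals.size - np.searchsorted(sorted_vals, bins - 1e-9, side="left")
    pct = 100.0 * n_ge / vals.size
    vol_cc = vals.size * dose.grid.voxel_volume_cc
    return DvhCurve(roi_name=mask.name, dose_bins_gy=bins,
                    cumulative_volume_pct=pct, roi_volume_cc=vol_cc)


def dvh_query(dose: DoseGrid, mask: RoiMask, *,
              d_pct: tuple[float, ...] = (2.0, 50.0, 98.0),
              v_gy: tuple[float, ...] = (),
              d_cc: tuple[float, ...] = (),
              bin_gy: float = DEFAULT_BIN_GY) -> dict[str, float]:
    """Named dose-volume statistics of one structure."""
    curve = cumulative_dvh(dose, mask, bin_gy=bin_gy)
    vals = _roi_dose_values(dose, mask)
    out: dict[str, float] = {
        "D_mean": float(vals.mean()),
        "D_max": float(vals.max()),
    }
    for p in d_pct:
        out[f"D_{p:g}%"] = curve.d_at(p)
    for x in v_gy:
        out[f"V_{x:g}Gy"] = curve.v_at(x)
    for v in d_cc:
        out[f"D_{v:g}cc"] = curve.d_cc(v)
    return out


def homogeneity_index(d2: float, d98: float, d50: float) -> float:
    """HI = (D_2% - D_98%) / D_50%; lower is more uniform."""
    if d50 <= 0:
        raise ValueError("D_50% must be positive")
    return (d2 - d98) / d50


@dataclass(frozen=True)
class IsodoseVolumes:
    tv_ptv_cc: float   # prescription isodose ∩ PTV
    v_ptv_cc: float    # PTV volume
    v_tvp_cc: float    # prescription isodose volume

    def __post_init__(self) -> None:
        if self.tv_ptv_cc > min(self.v_ptv_cc, self.v_tvp_cc) + 1e-9:
            raise ValueError("TV_PTV cannot exceed V_PTV or V_TVP")


def conformity_index(iv: IsodoseVolumes) -> float:
    """CI = TV_PTV^2 / (V_PTV * V_TVP); 1 is perfect conformity."""
    if iv.v_ptv_cc <= 0 or iv.v_tvp_cc <= 0:
        raise ValueError("V_PTV and V_TVP must be positive")
    return iv.tv_ptv_cc ** 2 / (iv.v_ptv_cc * iv.v_tvp_cc)


def gradient_index(v_x_cc: float, v_tvp_cc: float) -> float:
    """GI_x = V_x / V_TVP; smaller means faster dose drop-off."""
    if v_tvp_cc <= 0:
        raise ValueError("V_TVP must be positive")
    return v_x_cc / v_tvp_cc


def isodose_volumes(dose: DoseGrid, ptv: RoiMask, presc_gy: float) -> IsodoseVolumes:
    vox_cc = dose.grid.voxel_volume_cc
    iso = dose.values >= presc_gy * (1 - 1e-9)
    sel = resample_mask_to_grid(ptv, dose.grid) if ptv.grid != dose.grid \
        else ptv.voxels
    return IsodoseVolumes(
        tv_ptv_cc=float(np.count_nonzero(iso & sel)) * vox_cc,
        v_ptv_cc=float(np.count_nonzero(sel)) * vox_cc,
        v_tvp_cc=float(np.count_nonzero(iso)) * vox_cc,
    )


# ---------------------------------------------------------------------------
# protocol constraints
# ---------------------------------------------------------------------------

# (row label, structures involved, metric key, comparator, limit, hard?)
# limits for PTV D_max are percentages of the prescription dose.
PROTOCOL_ROWS = (
    ("PTV D_max <= 115%", ("PTV",), "dmax_pct", "<=", 115.0, True),
    ("PTV D_max <= 110%", ("PTV",), "dmax_pct", "<=", 110.0, False),
    ("PTV V_presc >= 95%", ("PTV",), "v_presc_pct", ">=", 95.0, False),
    ("bladder V_50Gy < 50%", ("bladder",), "v50_pct", "<", 50.0, True),
    ("bladder V_40Gy < 60%", ("bladder",), "v40_pct", "<", 60.0, False),
    ("rectum V_50Gy < 50%", ("rectum",), "v50_pct", "<", 50.0, True),
    ("rectum V_40Gy < 60%", ("rectum",), "v40_pct", "<", 60.0, False),
    ("bowel bag V_45Gy < 195 cc", ("bowel bag",), "v45_cc", "<", 195.0, True),
    ("femoral head V_50Gy < 5%", ("femoral head_L", "femoral head_R"),
     "v50_pct", "<", 5.0, True),
    ("kidney D_mean < 15 Gy", ("kidney_L", "kidney_R"), "dmean_gy", "<", 15.0, True),
    ("kidney D_mean < 10 Gy", ("kidney_L", "kidney_R"), "dmean_gy", "<", 10.0, False),
)


@dataclass(frozen=True)
class ConstraintVerdict:
    label: str
    value: float | None     # worst side for L/R rows; None if not evaluated
    limit: float
    hard: bool
    passed: bool | None     # None if not evaluated

    @property
    def evaluated(self) -> bool:
        return self.value is not None


@dataclass
class PlanMetrics:
    """The full evaluation bundle for one normalized plan."""

    prescription: Prescription
    per_roi: dict[str, dict[str, float]]
    hi: float
    ci: float
    gi: dict[float, float]
    verdicts: list[ConstraintVerdict]

    def verdict(self, label: str) -> ConstraintVerdict:
        for v in self.verdicts:
            if v.label == label:
                return v
        raise KeyError(label)

    def as_dict(self) -> dict:
        return {
            "prescription_gy": self.prescription.total_dose_gy,
            "per_roi": self.per_roi,
            "HI": self.hi,
            "CI": self.ci,
            "GI": {f"{k:g}": v for k, v in self.gi.items()},
            "constraints": [
                {"label": v.label, "value": v.value, "limit": v.limit,
                 "type": "hard" if v.hard else "soft", "passed": v.passed}
                for v in self.verdicts
            ],
        }


def _fraction_ge(vals: np.ndarray, threshold: float) -> float:
    """Volume fraction receiving >= threshold, linearly interpolated between
    voxel dose values (the exact inverse of the percentile convention used
    by the coverage normalization, so a plan normalized to 95 % coverage
    reads exactly 95 %)."""
    s = np.sort(np.asarray(vals, float))
    n = s.size
    if threshold <= s[0]:
        return 1.0
    if threshold > s[-1]:
        return 0.0
    if n == 1:
        return float(threshold <= s[0])
    pos = float(np.interp(threshold, s, np.arange(n) / (n - 1)))
    return 1.0 - pos


def _metric_for_row(dose: DoseGrid, mask: RoiMask, key: str, presc: float) -> float:
    vals = _roi_dose_values(dose, mask)
    if vals.size == 0:
        raise ValueError("empty")
    if key == "dmax_pct":
        return 100.0 * float(vals.max()) / presc
    if key == "v_presc_pct":
        return 100.0 * _fraction_ge(vals, presc)
    if key == "v50_pct":
        return 100.0 * _fraction_ge(vals, 50.0)
    if key == "v40_pct":
        return 100.0 * _fraction_ge(vals, 40.0)
    if key == "v45_cc":
        return _fraction_ge(vals, 45.0) * vals.size * dose.grid.voxel_volume_cc
    if key == "dmean_gy":
        return float(vals.mean())
    raise ValueError(f"unknown metric key {key}")  # pragma: no cover


def check_protocol(dose: DoseGrid, case: PlanCase) -> list[ConstraintVerdict]:
    """Evaluate every protocol row; L/R rows report the worse side."""
    presc = case.prescription.total_dose_gy
    verdicts = []
    for label, rois, key, op, limit, hard in PROTOCOL_ROWS:
        values = []
        for name in rois:
            if name not in case.structures or case[name].is_empty:
                continue
            try:
                values.append(_metric_for_row(dose, case[name], key, presc))
            except ValueError:
                continue
        if not values:
            verdicts.append(ConstraintVerdict(label, None, limit, hard, None))
            continue
        worst = max(values) if op in ("<", "<=") else min(values)
        eps = 1e-6 * max(abs(limit), 1.0)  # float guard at exact-limit boundaries
        if op == "<":
            ok = worst < limit
        elif op == "<=":
            ok = worst <= limit + eps
        else:
            ok = worst >= limit - eps
        verdicts.append(ConstraintVerdict(label, float(worst), limit, hard, bool(ok)))
    return verdicts


OAR_QUERY = {
    "bladder": dict(v_gy=(50.0, 40.0), d_cc=(0.03,)),
    "rectum": dict(v_gy=(50.0, 40.0), d_cc=(0.03,)),
    "bowel bag": dict(v_gy=(45.0,), d_cc=(0.03,)),
    "femoral head_L": dict(v_gy=(50.0,)),
    "femoral head_R": dict(v_gy=(50.0,)),
    "kidney_L": dict(),
    "kidney_R": dict(),
}


def evaluate_plan(dose: DoseGrid, case: PlanCase) -> PlanMetrics:
    """Compute the full evaluation bundle for a normalized dose distribution.

    Pure function of (dose, case): per-ROI DVH statistics, HI/CI/GI indices
    and the protocol verdict table.  Accepts a ``Plan`` in place of the dose.
    """
    if hasattr(dose, "dose"):  # a Plan object
        dose = dose.dose
    presc = case.prescription.total_dose_gy
    per_roi: dict[str, dict[str, float]] = {}

    ptv_stats = dvh_query(dose, case["PTV"], d_pct=(2.0, 50.0, 95.0, 98.0),
                          v_gy=(presc,))
    # absolute bowel-bag V_45Gy in cc alongside the percentages
    per_roi["PTV"] = ptv_stats
    for name, q in OAR_QUERY.items():
        if name not in case.structures or case[name].is_empty:
            continue
        per_roi[name] = dvh_query(dose, case[name], **q)
    if "bowel bag" in per_roi:
        c = cumulative_dvh(dose, case["bowel bag"])
        per_roi["bowel bag"]["V_45Gy_cc"] = c.v_at(45.0) / 100.0 * c.roi_volume_cc

    hi = homogeneity_index(ptv_stats["D_2%"], ptv_stats["D_98%"], ptv_stats["D_50%"])
    iv = isodose_volumes(dose, case["PTV"], presc)
    ci = conformity_index(iv)
    vox_cc = dose.grid.voxel_volume_cc
    gi = {}
    for x in GRADIENT_THRESHOLDS_GY:
        v_x = float(np.count_nonzero(dose.values >= x * (1 - 1e-9))) * vox_cc
        gi[x] = gradient_index(v_x, iv.v_tvp_cc)

    return PlanMetrics(prescription=case.prescription, per_roi=per_roi,
                       hi=hi, ci=ci, gi=gi, verdicts=check_protocol(dose, case))
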