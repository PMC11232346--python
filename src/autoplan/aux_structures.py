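"""Auxiliary planning structures: rings, normal tissue, and the iterative
PTV-contraction loop that caps how much of each OAR remains inside the
(effective) target.

The preprocessing deliberately concentrates unavoidable PTV dose deficits in
the regions overlapping OARs: the PTV is contracted inward in 0.5 mm steps
until the bladder and rectum each keep at most 45 % of their volume inside
the contracted PTV, and the bowel bag keeps at most 110 cc.  For each OAR,
``oar_new = oar ∩ contracted PTV`` and ``oar-ptv = oar − oar_new``; the
effective target ``PTV_new`` is the PTV minus the union of the ``*-ptv``
structures.  Each OAR's contraction depth is found independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import (
    RoiMask, Overlap, distance_inside_mm, distance_outside_mm,
    contract_from_distance, intersect, subtract, overlap,
)
from .phantom import PlanCase

__all__ = [
    "CapResult",
    "AuxStructureSet",
    "cap_overlap",
    "build_aux_structures",
    "bag_objective_pct",
    "MissingStructureError",
]

_EPS = 1e-9

# contraction-loop safety cap: 400 steps of 0.5 mm = 20 cm, far beyond any pelvis
MAX_CONTRACTION_STEPS = 400

BLADDER_OVERLAP_CAP_PCT = 45.0
RECTUM_OVERLAP_CAP_PCT = 45.0
BOWELBAG_OVERLAP_CAP_CC = 110.0

AUX_STRUCTURE_NAMES = (
    "ring0.5", "ring1", "ring2", "ring3", "nt",
    "PTV_new", "PTV_new-3mm",
    "bladder-ptv", "rectum-ptv", "bowel bag-ptv",
    "bag", "bowel bag_PTV",
)


class MissingStructureError(KeyError):
    """A required ROI is absent from the case."""


@dataclass(frozen=True)
class CapResult:
    """Result of one OAR's contraction loop."""

    oar_new: RoiMask          # oar ∩ contracted PTV
    oar_minus_ptv: RoiMask    # oar − oar_new
    steps: int                # number of 0.5 mm contraction steps applied
    achieved: Overlap         # overlap(oar, contracted PTV) at termination


def _overlap_metric(n_int: int, n_oar: int, vox_cc: float, pct_mode: bool) -> float:
    if pct_mode:
        return 100.0 * n_int / n_oar
    return n_int * vox_cc


def cap_overlap(ptv: RoiMask, oar: RoiMask, *,
                threshold_pct: float | None = None,
                threshold_cc: float | None = None,
                step_mm: float = 0.5,
                max_steps: int = MAX_CONTRACTION_STEPS,
                ptv_inner_distance_mm: np.ndarray | None = None) -> CapResult:
    """Contract the PTV inward in ``step_mm`` increments until the OAR's
    overlap with the contracted PTV drops to the threshold; the returned step
    count is minimal.

    Exactly one of ``threshold_pct`` (percent of OAR volume) or
    ``threshold_cc`` (absolute cc) must be given.  ``ptv_inner_distance_mm``
    lets callers reuse a precomputed interior distance field of the PTV.
    """
    if (threshold_pct is None) == (threshold_cc is None):
        raise ValueError("give exactly one of threshold_pct or threshold_cc")
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    pct_mode = threshold_pct is not None
    threshold = threshold_pct if pct_mode else threshold_cc
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if ptv.grid != oar.grid:
        from .grid import GridMismatchError
        raise GridMismatchError("PTV and OAR are on different grids")

    n_oar = int(np.count_nonzero(oar.voxels))
    vox_cc = ptv.grid.voxel_volume_cc
    if n_oar == 0:
        if pct_mode:
            raise ValueError("OAR is empty: percent overlap undefined")
        empty = oar.with_voxels(np.zeros(oar.grid.shape, bool))
        return CapResult(empty, oar.with_voxels(oar.voxels.copy()), 0,
                         Overlap(None, 0.0))

    dist_in = (ptv_inner_distance_mm if ptv_inner_distance_mm is not None
               else distance_inside_mm(ptv))
    # distances of OAR∩PTV voxels to the PTV surface: overlap with the PTV
    # contracted by d keeps exactly the voxels with dist > d
    dvals = dist_in[oar.voxels & ptv.voxels]

    def metric_at(k: int) -> float:
        n_int = int(np.count_nonzero(dvals > k * step_mm + _EPS))
        return _overlap_metric(n_int, n_oar, vox_cc, pct_mode)

    steps = None
    for k in range(max_steps + 1):
        if metric_at(k) <= threshold + _EPS:
            steps = k
            break
    if steps is None:
        raise RuntimeError(
            f"contraction did not reach threshold within {max_steps} steps")

    contracted = (ptv if steps == 0
                  else contract_from_distance(ptv, dist_in, steps * step_mm))
    oar_new = intersect(oar, contracted, name=f"{oar.name}_new")
    oar_minus_ptv = subtract(oar, oar_new, name=f"{oar.name}-ptv")
    return CapResult(oar_new=oar_new, oar_minus_ptv=oar_minus_ptv, steps=steps,
                     achieved=overlap(oar, contracted))


def bag_objective_pct(v_bag_cc: float) -> int | None:
    """Per-patient DVH volume parameter for the bowel-helper structure:
    floor(100 * 195 / V_bag) percent, clamped to [0, 100].  Returns None
    (objective omitted) when the structure is empty."""
    if v_bag_cc <= 0:
        return None
    return int(min(100, max(0, math.floor(100.0 * 195.0 / v_bag_cc))))


@dataclass
class AuxStructureSet:
    """The twelve auxiliary structures plus contraction bookkeeping."""

    masks: dict[str, RoiMask]
    contraction_steps: dict[str, int]
    achieved_overlaps: dict[str, float]
    v_bag_cc: float
    bag_volume_pct: int | None

    def __getitem__(self, name: str) -> RoiMask:
        return self.masks[name]

    # attribute aliases for the python-unfriendly display names
    @property
    def ring0_5(self) -> RoiMask: return self.masks["ring0.5"]
    @property
    def ring1(self) -> RoiMask: return self.masks["ring1"]
    @property
    def ring2(self) -> RoiMask: return self.masks["ring2"]
    @property
    def ring3(self) -> RoiMask: return self.masks["ring3"]
    @property
    def nt(self) -> RoiMask: return self.masks["nt"]
    @property
    def ptv_new(self) -> RoiMask: return self.masks["PTV_new"]
    @property
    def ptv_new_3mm(self) -> RoiMask: return self.masks["PTV_new-3mm"]
    @property
    def bladder_ptv(self) -> RoiMask: return self.masks["bladder-ptv"]
    @property
    def rectum_ptv(self) -> RoiMask: return self.masks["rectum-ptv"]
    @property
    def bowelbag_ptv(self) -> RoiMask: return self.masks["bowel bag-ptv"]
    @property
    def bag(self) -> RoiMask: return self.masks["bag"]
    @property
    def bowelbag_in_ptv(self) -> RoiMask: return self.masks["bowel bag_PTV"]


def build_aux_structures(case: PlanCase, *, step_mm: float = 0.5) -> AuxStructureSet:
    """Build the full auxiliary structure set for one case.

    Rings at 0-5 / 5-10 / 10-20 / 20-30 mm around the PTV, the remaining
    normal tissue ``nt``, the capped-overlap subtraction structures, the
    effective target ``PTV_new`` with its 3 mm interior, the bowel helper
    ``bag`` (bowel bag within 20 mm of the PTV) and ``bowel bag_PTV``.
    """
    for name in ("PTV", "bladder", "rectum", "bowel bag", "body"):
        if name not in case.structures:
            raise MissingStructureError(f"case is missing required structure {name!r}")

    ptv = case["PTV"]
    body = case["body"]
    grid = ptv.grid

    dist_out = distance_outside_mm(ptv)
    shells = {}
    prev = ptv.voxels
    for name, outer in (("ring0.5", 5.0), ("ring1", 10.0), ("ring2", 20.0),
                        ("ring3", 30.0)):
        expanded = ptv.voxels | (dist_out <= outer + _EPS)
        shells[name] = RoiMask(name, grid, (expanded & ~prev) & body.voxels)
        prev = expanded
    nt = RoiMask("nt", grid, body.voxels & ~prev)

    dist_in = distance_inside_mm(ptv)
    caps = {
        "bladder": cap_overlap(ptv, case["bladder"], threshold_pct=BLADDER_OVERLAP_CAP_PCT,
                               step_mm=step_mm, ptv_inner_distance_mm=dist_in),
        "rectum": cap_overlap(ptv, case["rectum"], threshold_pct=RECTUM_OVERLAP_CAP_PCT,
                              step_mm=step_mm, ptv_inner_distance_mm=dist_in),
        "bowel bag": cap_overlap(ptv, case["bowel bag"], threshold_cc=BOWELBAG_OVERLAP_CAP_CC,
                                 step_mm=step_mm, ptv_inner_distance_mm=dist_in),
    }
    removed = (caps["bladder"].oar_minus_ptv.voxels
               | caps["rectum"].oar_minus_ptv.voxels
               | caps["bowel bag"].oar_minus_ptv.voxels)
    ptv_new = RoiMask("PTV_new", grid, ptv.voxels & ~removed)
    ptv_new_3mm = contract_from_distance(
        ptv_new, distance_inside_mm(ptv_new), 3.0, name="PTV_new-3mm")

    bag = RoiMask("bag", grid,
                  case["bowel bag"].voxels & (ptv.voxels | (dist_out <= 20.0 + _EPS)))
    bowelbag_in_ptv = intersect(case["bowel bag"], ptv, name="bowel bag_PTV")

    v_bag = bag.volume_cc
    masks = {
        **shells,
        "nt": nt,
        "PTV_new": ptv_new,
        "PTV_new-3mm": ptv_new_3mm,
        "bladder-ptv": caps["bladder"].oar_minus_ptv.with_voxels(
            caps["bladder"].oar_minus_ptv.voxels, "bladder-ptv"),
        "rectum-ptv": caps["rectum"].oar_minus_ptv.with_voxels(
            caps["rectum"].oar_minus_ptv.voxels, "rectum-ptv"),
        "bowel bag-ptv": caps["bowel bag"].oar_minus_ptv.with_voxels(
            caps["bowel bag"].oar_minus_ptv.voxels, "bowel bag-ptv"),
        "bag": bag,
        "bowel bag_PTV": bowelbag_in_ptv,
    }
    # deterministic display order
    masks = {name: masks[name] for name in AUX_STRUCTURE_NAMES}

    achieved = {
        "bladder_overlap_pct": caps["bladder"].achieved.fraction_pct,
        "rectum_overlap_pct": caps["rectum"].achieved.fraction_pct,
        "bowelbag_overlap_cc": caps["bowel bag"].achieved.volume_cc,
    }
    steps = {name: caps[name].steps for name in ("bladder", "rectum", "bowel bag")}
    return AuxStructureSet(masks=masks, contraction_steps=steps,
                           achieved_overlaps=achieved, v_bag_cc=v_bag,
                           bag_volume_pct=bag_objective_pct(v_bag))
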