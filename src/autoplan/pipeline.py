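"""End-to-end orchestration: phantom → auxiliary structures → influence →
template → two-round optimization → 95 % normalization → evaluation,
with a single serializable run report.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .aux_structures import AuxStructureSet, build_aux_structures
from .dose import BeamConfig, DoseGrid, build_influence
from .evaluation import PlanMetrics, evaluate_plan
from .grid import save_structures
from .objectives import (ObjectiveKind, ObjectiveSpec, ObjectiveTemplate,
                         default_template)
from .optimizer import (OptimizerConfig, Plan, normalize_to_coverage,
                        optimize_plan)
from .phantom import PhantomConfig, PlanCase, Prescription, generate_case

__all__ = [
    "RunConfig",
    "RunResult",
    "run_pipeline",
    "load_template",
    "save_template",
    "TemplateParseError",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomConfig = PhantomConfig()
    beams: BeamConfig = BeamConfig()
    optimizer: OptimizerConfig = OptimizerConfig()
    template_path: str | None = None   # None = built-in template
    coverage_pct: float = 95.0
    out_dir: str | None = None
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """All stage outputs plus the serializable report."""

    case: PlanCase
    aux: AuxStructureSet
    plan: Plan
    metrics: PlanMetrics
    report: dict


def run_pipeline(config: RunConfig, case: PlanCase | None = None) -> RunResult:
    """Execute the full automated-planning workflow for one case.

    Deterministic given the config and master seed.  When ``case`` is given
    the phantom stage is skipped (externally loaded structure sets).
    """
    timings: dict[str, float] = {}
    chash = config.config_hash()

    def _stage(name):
        class _T:
            def __enter__(self_t):
                self_t.t0 = time.perf_counter()
            def __exit__(self_t, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_t.t0
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return _T()

    if case is None:
        with _stage("phantom"):
            pcfg = dataclasses.replace(config.phantom, seed=config.seed)
            case = generate_case(pcfg)
    presc = case.prescription

    with _stage("aux_structures"):
        aux = build_aux_structures(case)
    with _stage("influence"):
        model = build_influence(case, config.beams)
    with _stage("template"):
        if config.template_path is not None:
            template = load_template(config.template_path)
        else:
            template = default_template(aux, presc)
    with _stage("optimize"):
        ocfg = dataclasses.replace(config.optimizer, seed=config.seed)
        plan = optimize_plan(case, aux, model, template, ocfg)
    with _stage("normalize"):
        dose, scale = normalize_to_coverage(plan.dose, case["PTV"], presc,
                                            config.coverage_pct)
        plan.dose = dose
        plan.normalization_scale = scale
        plan.weights = plan.weights * scale
    with _stage("evaluate"):
        metrics = evaluate_plan(plan.dose, case)

    report = {
        "config_hash": chash,
        "seed": config.seed,
        "prescription_gy": presc.total_dose_gy,
        "fractions": presc.fractions,
        "phantom": {
            "targets": case.provenance.get("targets"),
            "realized": case.provenance.get("realized"),
        },
        "preprocessing": {
            "contraction_steps": aux.contraction_steps,
            "achieved_overlaps": aux.achieved_overlaps,
            "v_bag_cc": aux.v_bag_cc,
            "bag_volume_pct": aux.bag_volume_pct,
        },
        "optimization": {
            "n_beamlets": len(plan.weights),
            "rounds": config.optimizer.rounds,
            "iterations_per_round": config.optimizer.iterations_per_round,
            "initial_objective": plan.objective_history[0],
            "final_objective": plan.objective_history[-1],
        },
        "normalization_scale": plan.normalization_scale,
        "metrics": metrics.as_dict(),
        "machine_metadata": plan.machine_metadata,
        "timings_s": timings,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_structures(case.structures, out / "structures",
                        extra_manifest={"prescription_gy": presc.total_dose_gy,
                                        "fractions": presc.fractions,
                                        "seed": config.seed,
                                        "config_hash": chash})
        save_structures(aux.masks, out / "aux_structures",
                        extra_manifest={"config_hash": chash})
        _save_dose_nifti(plan.dose, out / "dose.nii.gz")
        np.savetxt(out / "beamlet_weights.txt", plan.weights)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        _write_dvh_csv(plan.dose, case, out / "dvh.csv")
    return RunResult(case=case, aux=aux, plan=plan, metrics=metrics, report=report)


def run_cohort(config: RunConfig, n: int) -> list[RunResult]:
    """Run the pipeline on ``n`` phantoms with per-case seeds derived from
    the master seed.  With an output directory set, writes one plan bundle
    per case plus a comparison-ready per-case metrics table (CSV)."""
    from .phantom import cohort_seeds
    from .stats_compare import metrics_table

    if n < 1:
        raise ValueError("cohort size must be >= 1")
    base_out = Path(config.out_dir) if config.out_dir is not None else None
    results = []
    for i, seed in enumerate(cohort_seeds(config.seed, n)):
        sub = dataclasses.replace(
            config, seed=seed,
            out_dir=str(base_out / f"case_{i:03d}") if base_out else None)
        results.append(run_pipeline(sub))
    if base_out is not None:
        import pandas as pd
        table = metrics_table([r.metrics for r in results])
        df = pd.DataFrame(table, index=[f"case_{i:03d}" for i in range(n)])
        df.index.name = "case"
        df.to_csv(base_out / "cohort_metrics.csv")
    return results


def _save_dose_nifti(dose: DoseGrid, path: Path) -> None:
    import nibabel as nib
    affine = np.diag(list(dose.grid.spacing_mm) + [1.0])
    affine[:3, 3] = dose.grid.origin_mm
    nib.save(nib.Nifti1Image(dose.values.astype(np.float32), affine), path)


def _write_dvh_csv(dose: DoseGrid, case: PlanCase, path: Path,
                   bin_gy: float = 0.5) -> None:
    from .evaluation import cumulative_dvh
    curves = {}
    for name, mask in case.structures.items():
        if mask.is_empty:
            continue
        curves[name] = cumulative_dvh(dose, mask, bin_gy=bin_gy)
    dmax = max(float(c.dose_bins_gy[-1]) for c in curves.values())
    bins = np.arange(0.0, dmax + bin_gy, bin_gy)
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["dose_Gy"] + list(curves))
        for b in bins:
            w.writerow([f"{b:.2f}"] + [f"{c.v_at(b):.4f}" for c in curves.values()])


# ---------------------------------------------------------------------------
# objective-template files: CSV, one record per row
# ---------------------------------------------------------------------------

class TemplateParseError(ValueError):
    """Malformed objective-template file (message carries the line number)."""


_TEMPLATE_HEADER = ["roi", "kind", "target_gy", "volume_pct", "weight", "eud_a"]


def save_template(template: ObjectiveTemplate, path: str | Path) -> None:
    """Write a template as CSV (empty cells for inapplicable fields)."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(_TEMPLATE_HEADER + ["prescription_gy", "fractions"])
        for i, s in enumerate(template.specs):
            extra = ([f"{template.prescription.total_dose_gy:g}",
                      str(template.prescription.fractions)] if i == 0 else ["", ""])
            w.writerow([
                s.roi_name, s.kind.value, f"{s.target_gy:g}",
                "" if s.volume_pct is None else f"{s.volume_pct:g}",
                f"{s.weight:g}",
                "" if s.eud_a is None else f"{s.eud_a:g}",
            ] + extra)


def load_template(path: str | Path) -> ObjectiveTemplate:
    """Load an objective template; errors carry the offending line number."""
    path = Path(path)
    specs: list[ObjectiveSpec] = []
    presc = Prescription()
    with open(path, newline="") as f:
        reader = csv.reader(f)
        try:
            header = next(reader)
        except StopIteration:
            raise TemplateParseError(f"{path}: empty template file") from None
        if [h.strip() for h in header[:6]] != _TEMPLATE_HEADER:
            raise TemplateParseError(
                f"{path}: line 1: expected header {','.join(_TEMPLATE_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            row = [c.strip() for c in row] + [""] * (8 - len(row))
            roi, kind, target, volume, weight, eud_a = row[:6]
            try:
                kind_enum = ObjectiveKind(kind)
            except ValueError:
                raise TemplateParseError(
                    f"{path}: line {lineno}: unknown objective kind {kind!r}") from None
            try:
                spec = ObjectiveSpec(
                    roi_name=roi, kind=kind_enum,
                    target_gy=float(target),
                    weight=float(weight),
                    volume_pct=float(volume) if volume else None,
                    eud_a=float(eud_a) if eud_a else None,
                )
            except (ValueError, TypeError) as exc:
                raise TemplateParseError(
                    f"{path}: line {lineno}: {exc}") from None
            specs.append(spec)
            if row[6]:
                presc = Prescription(total_dose_gy=float(row[6]),
                                     fractions=int(row[7] or 28))
    if not specs:
        raise TemplateParseError(f"{path}: template has no objective rows")
    return ObjectiveTemplate(specs=specs, prescription=presc)
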