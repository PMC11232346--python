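"""Seeded generator of pelvic-like plan cases.

The generator does not attempt anatomical realism: it builds deformed
ellipsoids inside an elliptic-cylinder body and *places* the bladder,
rectum and bowel bag by bisection so that their overlap with the PTV hits
values drawn from the cohort distributions (truncated normals built from the
published mean +/- SD and range).  Those volume/overlap statistics are the
only properties of real patients that the downstream objective template
keys on.

Axis convention: axis 0 = left-right (x), axis 1 = anterior(-)/posterior(+)
(y), axis 2 = inferior(-)/superior(+) (z).  Coordinates are mm relative to
the body center.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import stats as sps

from .grid import Grid, RoiMask, morph, intersect, overlap

__all__ = [
    "Prescription",
    "TruncNormSpec",
    "PhantomConfig",
    "PlanCase",
    "GenerationError",
    "generate_case",
    "generate_cohort",
]


class GenerationError(RuntimeError):
    """Raised when a phantom's overlap targets are geometrically unsatisfiable."""


@dataclass(frozen=True)
class Prescription:
    """Prescribed total dose and fractionation (default 50.4 Gy in 28 fractions)."""

    total_dose_gy: float = 50.4
    fractions: int = 28

    def __post_init__(self) -> None:
        if self.total_dose_gy <= 0:
            raise ValueError("total dose must be positive")
        if self.fractions <= 0:
            raise ValueError("fraction count must be positive")

    @property
    def dose_per_fraction_gy(self) -> float:
        return self.total_dose_gy / self.fractions


def _trunc_moments(loc: float, scale: float, lo: float, hi: float) -> tuple[float, float]:
    a = -np.inf if lo is None else (lo - loc) / scale
    b = np.inf if hi is None else (hi - loc) / scale
    m, v = sps.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
    return float(m), float(np.sqrt(v))


@functools.lru_cache(maxsize=64)
def _fit_truncnorm(mean: float, sd: float, lo, hi) -> tuple[float, float]:
    """Underlying (loc, scale) whose *truncated* distribution best matches the
    requested mean/SD.  Truncation pulls the moments of a naively
    parameterized truncated normal away from the published cohort statistics
    (asymmetric ranges bias the mean), so the parameters are moment-matched
    by least squares."""
    from scipy import optimize

    if lo is None and hi is None:
        return mean, sd

    def resid(p):
        loc, log_scale = p
        m, s = _trunc_moments(loc, float(np.exp(log_scale)), lo, hi)
        return [(m - mean) / sd, (s - sd) / sd]

    sol = optimize.least_squares(resid, x0=[mean, np.log(sd)],
                                 xtol=1e-12, ftol=1e-12)
    return float(sol.x[0]), float(np.exp(sol.x[1]))


@dataclass(frozen=True)
class TruncNormSpec:
    """Distribution of one cohort statistic: normal truncated to [lo, hi],
    with the underlying parameters moment-matched so the truncated
    distribution itself has the requested mean and SD (as close as the
    bounds allow).  sd = 0 degenerates to the mean."""

    mean: float
    sd: float
    lo: float | None = None
    hi: float | None = None

    def _params(self) -> tuple[float, float]:
        return _fit_truncnorm(self.mean, self.sd, self.lo, self.hi)

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd <= 0:
            return self.mean
        loc, scale = self._params()
        a = -np.inf if self.lo is None else (self.lo - loc) / scale
        b = np.inf if self.hi is None else (self.hi - loc) / scale
        return float(sps.truncnorm.rvs(a, b, loc=loc, scale=scale, random_state=rng))

    def truncated_moments(self) -> tuple[float, float]:
        """(mean, sd) actually realized by the fitted truncated distribution."""
        if self.sd <= 0:
            return self.mean, 0.0
        loc, scale = self._params()
        return _trunc_moments(loc, scale, self.lo, self.hi)


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort statistics and geometry knobs for phantom generation.

    The distribution defaults are the cervical-cancer cohort statistics the
    pipeline is designed around: PTV volume 1347.45 +/- 179.28 cc
    (range 1122.82-1862.99), bladder-in-PTV 37 +/- 11 % (13-64), rectum-in-PTV
    52 +/- 13 % (24-72) and bowel-bag-in-PTV 115.79 +/- 52.09 cc (8.05-205.67).
    Organ volumes themselves are not part of the cohort report; typical adult
    values are used.
    """

    ptv_volume_cc: TruncNormSpec = TruncNormSpec(1347.45, 179.28, 1122.82, 1862.99)
    bladder_overlap_pct: TruncNormSpec = TruncNormSpec(37.0, 11.0, 13.0, 64.0)
    rectum_overlap_pct: TruncNormSpec = TruncNormSpec(52.0, 13.0, 24.0, 72.0)
    bowelbag_overlap_cc: TruncNormSpec = TruncNormSpec(115.79, 52.09, 8.05, 205.67)
    body_extent_mm: tuple[float, float, float] = (340.0, 240.0, 250.0)
    ctv_to_ptv_margin_mm: float = 7.0
    spacing_mm: float = 2.5
    bladder_volume_cc: float = 300.0
    rectum_volume_cc: float = 70.0
    bowelbag_volume_cc: float = 1300.0
    femoral_head_volume_cc: float = 55.0
    kidney_volume_cc: float = 150.0
    prescription: Prescription = Prescription()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ctv_to_ptv_margin_mm < 0:
            raise ValueError("CTV->PTV margin must be >= 0")
        if self.spacing_mm <= 0:
            raise ValueError("grid spacing must be positive")
        for nm in ("bladder_overlap_pct", "rectum_overlap_pct"):
            spec: TruncNormSpec = getattr(self, nm)
            if not (0 < spec.mean < 100):
                raise ValueError(f"{nm} mean must lie in (0, 100)")
        if self.ptv_volume_cc.mean <= 0 or self.bowelbag_overlap_cc.mean <= 0:
            raise ValueError("volume means must be positive")


@dataclass
class PlanCase:
    """Structure set + prescription + provenance: the pipeline's input record."""

    structures: dict[str, RoiMask]
    prescription: Prescription
    grid: Grid
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> RoiMask:
        try:
            return self.structures[name]
        except KeyError:
            raise KeyError(f"case has no structure named {name!r}") from None

    @property
    def names(self) -> list[str]:
        return list(self.structures)


CASE_STRUCTURES = (
    "CTV", "PTV", "bladder", "rectum", "bowel bag",
    "femoral head_L", "femoral head_R", "kidney_L", "kidney_R", "body",
)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _noise_field(rng: np.random.Generator, coords, amplitude: float,
                 n_modes: int, wavelength_mm: tuple[float, float]) -> np.ndarray:
    """Smooth multiplicative radius perturbation: a few random plane-wave
    cosines, normalized so the field stays within +/- amplitude."""
    x, y, z = coords
    out = np.zeros_like(x)
    for _ in range(n_modes):
        lam = rng.uniform(*wavelength_mm)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        k = 2 * np.pi / lam
        phase = rng.uniform(0, 2 * np.pi)
        out += np.cos(k * (d[0] * x + d[1] * y + d[2] * z) + phase)
    return amplitude * out / max(n_modes, 1)


def _semi_axes(volume_cc: float, ratios: tuple[float, float, float]) -> np.ndarray:
    """Ellipsoid semi-axes with the given shape ratios and target volume."""
    r = np.asarray(ratios, dtype=float)
    r /= np.prod(r) ** (1.0 / 3.0)
    base = (3.0 * volume_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return base * r


def _ellipsoid(coords, center, semi_axes, noise: np.ndarray | float = 0.0,
               scale: float = 1.0) -> np.ndarray:
    x, y, z = coords
    a, b, c = np.asarray(semi_axes) * scale
    q = (((x - center[0]) / a) ** 2 + ((y - center[1]) / b) ** 2
         + ((z - center[2]) / c) ** 2)
    return q <= (1.0 + noise) ** 2


def _bisect_monotone(fn, lo: float, hi: float, target: float, iters: int = 45):
    """Find t in [lo, hi] with fn(t) ~= target for fn nonincreasing in t.
    Returns (t, fn(t)).  Caller must have verified fn(lo) >= target >= fn(hi)."""
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if fn(mid) >= target:
            lo = mid
        else:
            hi = mid
    val = fn(lo)
    # lo keeps fn >= target; pick whichever bracket end lands closer
    val_hi = fn(hi)
    if abs(val_hi - target) < abs(val - target):
        return hi, val_hi
    return lo, val


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate_case(config: PhantomConfig) -> PlanCase:
    """Deterministically generate one pelvic phantom matching drawn cohort
    statistics (PTV volume, bladder/rectum overlap fractions, bowel-bag
    overlap volume) to well within 5 % relative."""
    rng = np.random.default_rng(config.seed)
    sp = float(config.spacing_mm)
    ext = np.asarray(config.body_extent_mm, dtype=float)
    scale_pos = ext / np.array([340.0, 240.0, 250.0])  # positions scale with body

    shape = tuple(int(np.round(e / sp)) + 4 for e in ext)
    origin = tuple(-(n * sp) / 2 + sp / 2 for n in shape)
    grid = Grid(shape=shape, spacing_mm=(sp, sp, sp), origin_mm=origin)
    coords = grid.coord_grids_mm()
    x, y, z = coords
    vox_cc = grid.voxel_volume_cc

    body_vox = (((x / (ext[0] / 2)) ** 2 + (y / (ext[1] / 2)) ** 2) <= 1.0) \
        & (np.abs(z) <= ext[2] / 2)
    body = RoiMask("body", grid, body_vox)

    # --- draws ------------------------------------------------------------
    ptv_target_cc = config.ptv_volume_cc.draw(rng)
    bladder_target_pct = config.bladder_overlap_pct.draw(rng)
    rectum_target_pct = config.rectum_overlap_pct.draw(rng)
    bowel_target_cc = config.bowelbag_overlap_cc.draw(rng)

    # --- CTV/PTV: scale CTV until the 7 mm-expanded PTV hits its volume ----
    ptv_center = np.array([0.0, 0.0, -30.0]) * scale_pos
    ctv_ratios = (1.10, 0.72, 1.00)
    ctv_noise = _noise_field(rng, coords, 0.05, 3, (90.0, 160.0))
    margin = config.ctv_to_ptv_margin_mm

    # initial semi-axes: shrink the drawn PTV volume by an estimated margin shell
    def ptv_volume_for(ctv_cc: float) -> tuple[float, RoiMask, RoiMask]:
        semi = _semi_axes(ctv_cc, ctv_ratios)
        ctv = RoiMask("CTV", grid, _ellipsoid(coords, ptv_center, semi, ctv_noise) & body_vox)
        ptv = intersect(morph(ctv, margin), body, name="PTV")
        return ptv.volume_cc, ctv, ptv

    semi0 = _semi_axes(ptv_target_cc, ctv_ratios)
    # analytic margin correction: V_PTV ~ prod(a_i + margin)/prod(a_i) * V_CTV
    shell = np.prod((semi0 + margin) / semi0)
    guess_cc = ptv_target_cc / shell
    vol, ctv, ptv = ptv_volume_for(guess_cc)
    for _ in range(6):
        if abs(vol - ptv_target_cc) / ptv_target_cc < 0.01:
            break
        guess_cc *= (ptv_target_cc / vol) ** 1.15  # slightly superlinear secant
        vol, ctv, ptv = ptv_volume_for(guess_cc)
    if abs(vol - ptv_target_cc) / ptv_target_cc > 0.05:
        raise GenerationError(
            f"could not match PTV volume target {ptv_target_cc:.1f} cc (got {vol:.1f} cc)")

    ptv_vox = ptv.voxels
    n_ptv = int(np.count_nonzero(ptv_vox))

    # --- OARs straddling the PTV boundary ---------------------------------
    def place_fraction(name, volume_cc_, ratios, direction, noise_amp, modes, wl,
                       target_pct) -> RoiMask:
        semi = _semi_axes(volume_cc_, ratios)
        noise = _noise_field(rng, coords, noise_amp, modes, wl)
        d = np.asarray(direction, dtype=float)
        d /= np.linalg.norm(d)
        t_hi = float(np.dot(np.abs(d), semi0 + margin) + np.dot(np.abs(d), semi) + 25.0)

        def frac_at(t: float) -> float:
            vox = _ellipsoid(coords, ptv_center + t * d, semi, noise) & body_vox
            n = int(np.count_nonzero(vox))
            if n == 0:
                return 0.0
            return 100.0 * np.count_nonzero(vox & ptv_vox) / n

        f_lo, f_hi = frac_at(0.0), frac_at(t_hi)
        if not (f_lo >= target_pct >= f_hi):
            raise GenerationError(
                f"{name}: overlap target {target_pct:.1f}% outside achievable "
                f"range [{f_hi:.1f}, {f_lo:.1f}]%")
        t, achieved = _bisect_monotone(frac_at, 0.0, t_hi, target_pct)
        if abs(achieved - target_pct) > 0.05 * max(target_pct, 1.0):
            raise GenerationError(
                f"{name}: achieved overlap {achieved:.2f}% misses target {target_pct:.2f}%")
        return RoiMask(name, grid,
                       _ellipsoid(coords, ptv_center + t * d, semi, noise) & body_vox)

    bladder = place_fraction("bladder", config.bladder_volume_cc, (1.05, 0.95, 0.90),
                             (0.0, -1.0, -0.15), 0.05, 3, (70.0, 140.0),
                             bladder_target_pct)
    rectum = place_fraction("rectum", config.rectum_volume_cc, (0.6, 0.6, 1.9),
                            (0.0, 1.0, -0.10), 0.04, 3, (60.0, 120.0),
                            rectum_target_pct)

    # --- bowel bag: superior blob, placed on absolute overlap volume ------
    bowel_semi = _semi_axes(config.bowelbag_volume_cc, (1.30, 0.95, 0.80))
    bowel_noise = _noise_field(rng, coords, 0.12, 5, (40.0, 90.0))
    excl = bladder.voxels | rectum.voxels

    def bowel_cc_at(dz: float) -> float:
        c = ptv_center + np.array([0.0, -5.0 * scale_pos[1], dz])
        vox = _ellipsoid(coords, c, bowel_semi, bowel_noise) & body_vox & ~excl
        return np.count_nonzero(vox & ptv_vox) * vox_cc

    dz_lo = 0.0
    dz_hi = float(semi0[2] + margin + bowel_semi[2] + 25.0)
    c_lo, c_hi = bowel_cc_at(dz_lo), bowel_cc_at(dz_hi)
    if not (c_lo >= bowel_target_cc >= c_hi):
        raise GenerationError(
            f"bowel bag: overlap target {bowel_target_cc:.1f} cc outside achievable "
            f"range [{c_hi:.1f}, {c_lo:.1f}] cc")
    dz, achieved_cc = _bisect_monotone(bowel_cc_at, dz_lo, dz_hi, bowel_target_cc)
    if abs(achieved_cc - bowel_target_cc) > 0.05 * bowel_target_cc:
        raise GenerationError(
            f"bowel bag: achieved overlap {achieved_cc:.1f} cc misses "
            f"target {bowel_target_cc:.1f} cc")
    bowel_center = ptv_center + np.array([0.0, -5.0 * scale_pos[1], dz])
    bowel = RoiMask("bowel bag", grid,
                    _ellipsoid(coords, bowel_center, bowel_semi, bowel_noise)
                    & body_vox & ~excl)

    # --- femoral heads and kidneys: fixed positions, forced outside PTV ----
    fem_r = (3.0 * config.femoral_head_volume_cc * 1000.0 / (4 * np.pi)) ** (1 / 3)
    structures: dict[str, RoiMask] = {}
    for side, sx in (("L", -1.0), ("R", 1.0)):
        c = ptv_center + np.array([sx * 110.0 * scale_pos[0], -5.0, -10.0])
        vox = _ellipsoid(coords, c, (fem_r, fem_r, fem_r)) & body_vox & ~ptv_vox
        structures[f"femoral head_{side}"] = RoiMask(f"femoral head_{side}", grid, vox)

    kid_semi = _semi_axes(config.kidney_volume_cc, (0.85, 0.70, 1.70))
    kid_z = 0.5 * ext[2] - kid_semi[2] - 5.0
    for side, sx in (("L", -1.0), ("R", 1.0)):
        c = np.array([sx * 80.0 * scale_pos[0], 15.0 * scale_pos[1], kid_z])
        vox = _ellipsoid(coords, c, kid_semi) & body_vox & ~ptv_vox
        structures[f"kidney_{side}"] = RoiMask(f"kidney_{side}", grid, vox)

    structures = {
        "CTV": ctv, "PTV": ptv, "bladder": bladder, "rectum": rectum,
        "bowel bag": bowel, **structures, "body": body,
    }
    for name in CASE_STRUCTURES:
        if structures[name].is_empty:
            raise GenerationError(f"generated structure {name!r} is empty")

    realized = {
        "ptv_volume_cc": ptv.volume_cc,
        "bladder_overlap_pct": overlap(bladder, ptv).fraction_pct,
        "rectum_overlap_pct": overlap(rectum, ptv).fraction_pct,
        "bowelbag_overlap_cc": overlap(bowel, ptv).volume_cc,
    }
    targets = {
        "ptv_volume_cc": ptv_target_cc,
        "bladder_overlap_pct": bladder_target_pct,
        "rectum_overlap_pct": rectum_target_pct,
        "bowelbag_overlap_cc": bowel_target_cc,
    }
    prov = {"config": asdict(config), "seed": config.seed,
            "targets": targets, "realized": realized}
    return PlanCase(structures=structures, prescription=config.prescription,
                    grid=grid, provenance=prov)


def cohort_seeds(master_seed: int, n: int) -> list[int]:
    """Per-case seeds derived reproducibly from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2 ** 31)) for child in ss.spawn(n)]


def generate_cohort(config: PhantomConfig, n: int) -> list[PlanCase]:
    """Generate ``n`` cases with per-case seeds derived from ``config.seed``."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    return [generate_case(replace(config, seed=s)) for s in cohort_seeds(config.seed, n)]
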