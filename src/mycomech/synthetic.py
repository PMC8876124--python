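"""Virtual compression studies and particle populations with known truth.

Every downstream stage (reduction, constitutive identification, FEM
cross-checks, particle statistics) is exercisable against data whose
ground truth is known exactly, because no public raw dataset for
mycelium-composite compression exists.  The generator emulates the lab
protocol: cylindrical specimens of ~70 mm diameter and 60–70 mm height
with slightly slanted top faces, a universal testing machine sampling a
load–displacement record on a uniform 0.1 mm grid until either a 1.8 kN
force limit or a condition-specific displacement limit is reached, at
least six biological replicates per substrate × particle-size condition,
and an expanded-polystyrene (EPS) benchmark group.

Forward model per specimen: a soft surface-mycelium "toe" layer engages
first (exponential engagement, two parameters), after which the bulk
follows the compressible Neo-Hookean closed form — the nominal force is

    F(u) = A0 · |λ S33(λ; c, d)|,   λ = 1 − ε_eff(u),

with multiplicative lognormal measurement noise and lognormal
between-specimen scatter on (c, d).  All scatter models are
positivity-preserving by construction.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .neohooke import NeoHookeParams, uniaxial_stress
from .reduction import LoadDisplacementCurve, SpecimenGeometry, read_load_displacement

__all__ = [
    "GroundTruth",
    "GeometryRanges",
    "StudyDesign",
    "SyntheticStudy",
    "ParticleShapeParams",
    "PARTICLE_PRESETS",
    "DEFAULT_CONDITIONS",
    "generate_specimen",
    "simulate_load_displacement",
    "generate_study",
    "generate_particles",
    "eps_benchmark_stress",
    "write_study",
    "read_study",
]

#: machine sampling step, mm — far finer than any feature analysed
DISPLACEMENT_STEP_MM = 0.1


@dataclass(frozen=True)
class GroundTruth:
    """True generating parameters of one condition.

    c, d (MPa) are the Neo-Hookean pair; toe_depth (mm) and toe_sharpness
    model the engagement of the soft surface-mycelium layer; noise_cv is
    the coefficient of variation of the multiplicative force noise;
    replicate_cv that of the lognormal between-specimen scatter on (c, d).
    """

    c: float
    d: float
    toe_depth: float = 2.0
    toe_sharpness: float = 3.0
    noise_cv: float = 0.02
    replicate_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.c <= 0 or self.d <= 0:
            raise ValueError("c and d must be positive")
        if self.toe_depth < 0:
            raise ValueError("toe_depth must be non-negative")
        if self.toe_sharpness <= 0:
            raise ValueError("toe_sharpness must be positive")
        if self.noise_cv < 0 or self.replicate_cv < 0:
            raise ValueError("coefficients of variation must be non-negative")

    @property
    def params(self) -> NeoHookeParams:
        return NeoHookeParams(c=self.c, d=self.d)


@dataclass(frozen=True)
class GeometryRanges:
    """Uniform sampling ranges for specimen geometry (mm, degrees)."""

    diameter: tuple[float, float] = (69.0, 71.0)
    height: tuple[float, float] = (60.0, 70.0)
    slant_deg: tuple[float, float] = (0.0, 3.0)

    def __post_init__(self) -> None:
        for name in ("diameter", "height", "slant_deg"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range has min > max: ({lo}, {hi})")


@dataclass(frozen=True)
class StudyDesign:
    """Conditions, replication and machine stop rules of a virtual study."""

    conditions: tuple[str, ...]
    replicates_per_condition: int = 6
    force_limit: float = 1800.0
    displacement_limits: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    geometry: GeometryRanges = field(default_factory=GeometryRanges)
    include_eps_benchmark: bool = True

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("study needs at least one condition")
        if self.replicates_per_condition < 1:
            raise ValueError("need at least one replicate per condition")
        if self.force_limit <= 0:
            raise ValueError("force limit must be positive")

    def displacement_limit(self, condition: str) -> float:
        return self.displacement_limits.get(condition, 40.0)


#: the six substrate × particle-size conditions of the lab study, with the
#: machine displacement stops used for each (mm); R = rapeseed straw,
#: H = hemp shives; S/M/L = small/medium/large particle fraction
DEFAULT_DISPLACEMENT_LIMITS = {
    "RS": 32.0, "RM": 42.0, "RL": 44.0,
    "HS": 30.0, "HM": 35.0, "HL": 40.0,
}

#: per-condition generating parameters.  Magnitudes are foam-scale
#: (strengths of order 0.05–0.15 MPa) with the qualitative ordering seen in
#: such composites — smaller particles stiffen the composite, and large
#: hemp shives outperform large rapeseed straw.  Not a fit to any dataset.
DEFAULT_CONDITIONS: dict[str, GroundTruth] = {
    "RS": GroundTruth(c=0.090, d=0.090),
    "RM": GroundTruth(c=0.070, d=0.070),
    "RL": GroundTruth(c=0.038, d=0.038),
    "HS": GroundTruth(c=0.070, d=0.070),
    "HM": GroundTruth(c=0.050, d=0.050),
    "HL": GroundTruth(c=0.046, d=0.046),
}


def default_design(seed: int = 0, replicates: int = 6) -> StudyDesign:
    """The standard virtual study: 6 conditions × ``replicates`` + EPS."""
    return StudyDesign(
        conditions=tuple(DEFAULT_CONDITIONS),
        replicates_per_condition=replicates,
        displacement_limits=dict(DEFAULT_DISPLACEMENT_LIMITS),
        seed=seed,
    )


def generate_specimen(
    rng: np.random.Generator, ranges: GeometryRanges = GeometryRanges()
) -> SpecimenGeometry:
    """Sample a specimen geometry uniformly within the given ranges."""
    d = rng.uniform(*ranges.diameter)
    h = rng.uniform(*ranges.height)
    s = rng.uniform(*ranges.slant_deg)
    return SpecimenGeometry(diameter=d, height=h, slant_deg=s)


def _toe_displacement(u: np.ndarray, depth: float, sharpness: float) -> np.ndarray:
    """Displacement absorbed by the soft surface layer, saturating at depth."""
    if depth == 0.0:
        return np.zeros_like(u)
    return depth * (1.0 - np.exp(-sharpness * u / depth))


def simulate_load_displacement(
    gt: GroundTruth,
    geometry: SpecimenGeometry,
    rng: np.random.Generator,
    force_limit: float = 1800.0,
    displacement_limit: float = 40.0,
    condition: str = "",
    specimen_id: str = "",
    params: NeoHookeParams | None = None,
) -> LoadDisplacementCurve:
    """One machine record from the closed-form forward model.

    With ``noise_cv = 0`` and ``toe_depth = 0`` the record equals the
    analytic model exactly, so reduce→fit round trips are testable to
    machine precision.  ``params`` overrides (c, d) for replicate scatter;
    the toe/noise settings always come from ``gt``.
    """
    if geometry.area <= 0 or geometry.height <= 0:
        raise ValueError("specimen must have positive area and height")
    p = params or gt.params
    L0 = geometry.height
    u = np.arange(0.0, displacement_limit + 0.5 * DISPLACEMENT_STEP_MM,
                  DISPLACEMENT_STEP_MM)
    u_toe = _toe_displacement(u, gt.toe_depth, gt.toe_sharpness)
    eps_eff = np.maximum(0.0, (u - u_toe) / L0)
    lam = 1.0 - eps_eff
    force = np.where(
        eps_eff > 0,
        geometry.area * np.abs(lam * uniaxial_stress(np.maximum(lam, 1e-6), p)),
        0.0,
    )
    if gt.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + gt.noise_cv**2))
        force = force * rng.lognormal(-0.5 * sigma**2, sigma, size=force.size)
    # truncate at the first sample triggering a stop rule (sample included)
    hit = np.nonzero(force >= force_limit)[0]
    if hit.size:
        end, stop_reason = int(hit[0]), "force_limit"
    else:
        end, stop_reason = u.size - 1, "displacement_limit"
    u, force = u[: end + 1], force[: end + 1]

    # post-test height: part of the peak strain remains as plastic set
    eps_max = u[-1] / L0
    recovery_fraction = rng.uniform(0.5, 0.7)
    plastic = (1.0 - recovery_fraction) * eps_max
    geometry = dataclasses.replace(geometry, post_test_height=L0 * (1.0 - plastic))

    return LoadDisplacementCurve(
        displacement=u,
        force=force,
        geometry=geometry,
        condition=condition,
        specimen_id=specimen_id,
        stop_reason=stop_reason,
    )


@dataclass
class SyntheticStudy:
    """A generated study: curves grouped by condition, plus the truth."""

    design: StudyDesign
    truth: dict[str, GroundTruth]
    curves: dict[str, list[LoadDisplacementCurve]]
    replicate_params: dict[str, list[NeoHookeParams]]

    @property
    def n_curves(self) -> int:
        return sum(len(v) for v in self.curves.values())


def _scatter_params(
    base: NeoHookeParams, cv: float, rng: np.random.Generator
) -> NeoHookeParams:
    if cv == 0:
        return base
    sigma = math.sqrt(math.log(1.0 + cv**2))
    fc, fd = rng.lognormal(-0.5 * sigma**2, sigma, size=2)
    return NeoHookeParams(c=base.c * fc, d=base.d * fd)


def generate_study(
    design: StudyDesign, truth: dict[str, GroundTruth] | None = None
) -> SyntheticStudy:
    """Generate a full virtual study, reproducible from ``design.seed``.

    Each condition's replicates draw (c, d) from mean-one lognormal scatter
    around the condition means.  When ``design.include_eps_benchmark`` is
    set, an extra "EPS" group with a linear–plateau–densification response
    is appended for comparative reports (it has no Neo-Hookean truth).
    """
    if truth is None:
        truth = {k: DEFAULT_CONDITIONS[k] for k in design.conditions}
    missing = [c for c in design.conditions if c not in truth]
    if missing:
        raise ValueError(f"no ground truth for conditions: {missing}")

    root = np.random.SeedSequence(design.seed)
    children = root.spawn(len(design.conditions) + 1)
    curves: dict[str, list[LoadDisplacementCurve]] = {}
    rep_params: dict[str, list[NeoHookeParams]] = {}
    for cond, child in zip(design.conditions, children):
        rng = np.random.default_rng(child)
        gt = truth[cond]
        curves[cond] = []
        rep_params[cond] = []
        for i in range(design.replicates_per_condition):
            geom = generate_specimen(rng, design.geometry)
            p = _scatter_params(gt.params, gt.replicate_cv, rng)
            rep_params[cond].append(p)
            curves[cond].append(
                simulate_load_displacement(
                    gt,
                    geom,
                    rng,
                    force_limit=design.force_limit,
                    displacement_limit=design.displacement_limit(cond),
                    condition=cond,
                    specimen_id=f"{cond}-{i + 1:02d}",
                    params=p,
                )
            )
    if design.include_eps_benchmark:
        rng = np.random.default_rng(children[-1])
        curves["EPS"] = [
            _simulate_eps(rng, design, f"EPS-{i + 1:02d}")
            for i in range(design.replicates_per_condition)
        ]
    return SyntheticStudy(
        design=design, truth=dict(truth), curves=curves, replicate_params=rep_params
    )


def eps_benchmark_stress(
    strain,
    modulus: float = 2.37,
    yield_stress: float = 0.08,
    plateau_slope: float = 0.06,
    densification_onset: float = 0.45,
    densification_quad: float = 16.8,
):
    """Three-segment EPS-like stress response (MPa).

    Linear rise at ``modulus`` to the yield stress, a gently sloped plateau,
    then quadratic densification beyond the onset strain.  Defaults give the
    familiar EPS picture: a stiff start (E ≈ 2.4 MPa), ~0.09 MPa carried at
    20 % strain, ~0.15 MPa at 50 %.  Report plumbing only — no constitutive
    meaning.
    """
    eps = np.asarray(strain, float)
    e_y = yield_stress / modulus
    plateau = yield_stress + plateau_slope * (eps - e_y)
    dens = plateau + densification_quad * np.maximum(0.0, eps - densification_onset) ** 2
    return np.where(eps < e_y, modulus * eps, dens)


def _simulate_eps(
    rng: np.random.Generator, design: StudyDesign, specimen_id: str
) -> LoadDisplacementCurve:
    geom = generate_specimen(rng, design.geometry)
    scale = rng.lognormal(0.0, 0.02)  # EPS scatters far less than composites
    limit = design.displacement_limits.get("EPS", 35.0)
    u = np.arange(0.0, limit + 0.5 * DISPLACEMENT_STEP_MM, DISPLACEMENT_STEP_MM)
    eps = u / geom.height
    force = geom.area * scale * eps_benchmark_stress(eps)
    noise = rng.lognormal(-0.5 * 0.01**2, 0.01, size=force.size)
    force = force * noise
    hit = np.nonzero(force >= design.force_limit)[0]
    end = hit[0] if hit.size else u.size - 1
    stop = "force_limit" if hit.size else "displacement_limit"
    geom = dataclasses.replace(geom, post_test_height=geom.height * (1 - 0.3 * eps[end]))
    return LoadDisplacementCurve(
        displacement=u[: end + 1],
        force=force[: end + 1],
        geometry=geom,
        condition="EPS",
        specimen_id=specimen_id,
        stop_reason=stop,
    )


# ---------------------------------------------------------------------------
# particle populations


@dataclass(frozen=True)
class ParticleShapeParams:
    """Lognormal length/aspect model of a milled plant-particle population.

    ``length_median_mm``/``length_sigma`` set the long-axis distribution,
    ``aspect_median``/``aspect_sigma`` the width/length ratio (clipped to at
    most 1), ``jitter`` the relative vertex perturbation of the rectangle
    outline.
    """

    length_median_mm: float = 8.0
    length_sigma: float = 0.30
    aspect_median: float = 0.35
    aspect_sigma: float = 0.35
    jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.length_median_mm <= 0 or self.aspect_median <= 0:
            raise ValueError("medians must be positive")
        if self.length_sigma < 0 or self.aspect_sigma < 0 or self.jitter < 0:
            raise ValueError("spreads must be non-negative")


#: hemp shives are thinner and more elongated than rapeseed straw pieces,
#: so their modal width/length (≈ min/max Feret) ratio sits lower
PARTICLE_PRESETS: dict[str, ParticleShapeParams] = {
    "hemp_like": ParticleShapeParams(
        length_median_mm=10.0, length_sigma=0.35,
        aspect_median=0.25, aspect_sigma=0.30, jitter=0.05,
    ),
    "rapeseed_like": ParticleShapeParams(
        length_median_mm=5.5, length_sigma=0.45,
        aspect_median=0.50, aspect_sigma=0.40, jitter=0.05,
    ),
}


def generate_particles(
    shape: ParticleShapeParams | str,
    n: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Sample ``n`` particle outlines (vertex arrays, mm) for one condition.

    Each particle is a rotated rectangle with jittered vertices — convex for
    the small default jitter.  Accepts a preset name ("hemp_like",
    "rapeseed_like") or explicit :class:`ParticleShapeParams`.
    """
    if n < 1:
        raise ValueError("need at least one particle")
    if isinstance(shape, str):
        try:
            shape = PARTICLE_PRESETS[shape]
        except KeyError:
            raise ValueError(
                f"unknown preset {shape!r}; available: {sorted(PARTICLE_PRESETS)}"
            ) from None
    out: list[np.ndarray] = []
    for _ in range(n):
        length = shape.length_median_mm * rng.lognormal(0.0, shape.length_sigma)
        aspect = min(1.0, shape.aspect_median * rng.lognormal(0.0, shape.aspect_sigma))
        width = aspect * length
        half = np.array(
            [[-length / 2, -width / 2], [length / 2, -width / 2],
             [length / 2, width / 2], [-length / 2, width / 2]]
        )
        if shape.jitter > 0:
            half = half * (1.0 + shape.jitter * rng.uniform(-1, 1, size=half.shape))
        theta = rng.uniform(0.0, math.pi)
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        out.append(half @ rot.T)
    return out


# ---------------------------------------------------------------------------
# on-disk layout: one two-column CSV per specimen plus a JSON manifest


def write_study(study: SyntheticStudy, outdir: str | Path) -> Path:
    """Write a study as per-specimen CSVs plus ``manifest.json``.

    Layout round-trips through :func:`read_study` /
    :func:`mycomech.reduction.read_load_displacement`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": study.design.seed, "conditions": {}}
    for cond, group in study.curves.items():
        entries = []
        for curve, p in zip(
            group,
            study.replicate_params.get(cond, [None] * len(group)),
        ):
            fname = f"{curve.specimen_id}.csv"
            header = "displacement_mm,force_N"
            np.savetxt(
                outdir / fname,
                np.column_stack([curve.displacement, curve.force]),
                delimiter=",",
                header=header,
                comments="",
                fmt="%.6f",
            )
            g = curve.geometry
            entries.append(
                {
                    "file": fname,
                    "specimen_id": curve.specimen_id,
                    "stop_reason": curve.stop_reason,
                    "geometry": {
                        "diameter_mm": g.diameter,
                        "height_mm": g.height,
                        "slant_deg": g.slant_deg,
                        "post_test_height_mm": g.post_test_height,
                    },
                    "true_params": None if p is None else {"c_MPa": p.c, "d_MPa": p.d},
                }
            )
        gt = study.truth.get(cond)
        manifest["conditions"][cond] = {
            "ground_truth": None
            if gt is None
            else {
                "c_MPa": gt.c, "d_MPa": gt.d,
                "toe_depth_mm": gt.toe_depth, "toe_sharpness": gt.toe_sharpness,
                "noise_cv": gt.noise_cv, "replicate_cv": gt.replicate_cv,
            },
            "specimens": entries,
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def read_study(indir: str | Path) -> dict[str, list[LoadDisplacementCurve]]:
    """Read back a study written by :func:`write_study`."""
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    curves: dict[str, list[LoadDisplacementCurve]] = {}
    for cond, entry in manifest["conditions"].items():
        group = []
        for spec in entry["specimens"]:
            g = spec["geometry"]
            geom = SpecimenGeometry(
                diameter=g["diameter_mm"],
                height=g["height_mm"],
                slant_deg=g["slant_deg"],
                post_test_height=g["post_test_height_mm"],
            )
            curve = read_load_displacement(
                indir / spec["file"],
                geometry=geom,
                condition=cond,
                specimen_id=spec["specimen_id"],
            )
            curve.stop_reason = spec["stop_reason"]
            group.append(curve)
        curves[cond] = group
    return curves
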