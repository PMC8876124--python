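"""Reduction of compression-test records to foam-mechanics summaries.

Machine load–displacement records (mm, N) are converted to engineering
stress–strain curves (σ = F/A0 in MPa, ε = ΔL/L0) and summarized the way
DIN 50134-style foam testing does it: an elastic modulus fitted between
10 % strain and an elastic-recovery-derived upper bound, the compressive
strength σ_st read at 20 % strain, the stress carried at 50 % strain, and
per-condition mean curves with pointwise Student-t 95 % confidence bands.

Compression is positive throughout this module: ε = ΔL/L0 with ΔL the
height decrease, and stresses are stored as magnitudes.  The stretch
convention λ = 1 − ε is applied once, at the constitutive-fit boundary.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SpecimenGeometry",
    "LoadDisplacementCurve",
    "StressStrainCurve",
    "MechanicalSummary",
    "MeanCurve",
    "to_stress_strain",
    "elastic_modulus",
    "compressive_strength",
    "stress_at_strain",
    "recovery_split",
    "mean_curve",
    "summarize",
    "read_load_displacement",
]

#: machine pre-load in N; samples before the first crossing are trimmed
PRELOAD_N = 1.0


@dataclass(frozen=True)
class SpecimenGeometry:
    """Cylindrical specimen geometry, lengths in mm.

    ``slant_deg`` is the inclination of the top face (specimens settle
    slightly while growing free-standing), ``post_test_height`` the height
    measured immediately after unloading.
    """

    diameter: float
    height: float
    slant_deg: float = 0.0
    post_test_height: float | None = None

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if not (0.0 <= self.slant_deg < 10.0):
            raise ValueError("slant angle must lie in [0, 10) degrees")
        if self.post_test_height is not None and self.post_test_height > self.height:
            raise ValueError("post-test height cannot exceed the initial height")

    @property
    def area(self) -> float:
        """Cross-sectional area A0 = π D0²/4 in mm²."""
        return math.pi * self.diameter**2 / 4.0


@dataclass
class LoadDisplacementCurve:
    """Raw machine record: displacement (mm) vs compressive force (N)."""

    displacement: np.ndarray
    force: np.ndarray
    geometry: SpecimenGeometry
    condition: str = ""
    specimen_id: str = ""
    stop_reason: str = ""  # "force_limit" | "displacement_limit" | ""

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, float)
        self.force = np.asarray(self.force, float)
        if self.displacement.shape != self.force.shape or self.displacement.ndim != 1:
            raise ValueError("displacement and force must be equal-length 1-D arrays")
        if self.displacement.size < 2:
            raise ValueError("need at least 2 samples")
        if self.displacement[0] < 0:
            raise ValueError("displacement must start at or above 0")
        if np.any(np.diff(self.displacement) < 0):
            raise ValueError("displacement must be monotone non-decreasing")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("forces must be finite")


@dataclass
class StressStrainCurve:
    """Engineering stress–strain pairs; σ in MPa (magnitude), ε in [0, 1)."""

    strain: np.ndarray
    stress: np.ndarray
    area: float
    height: float
    condition: str = ""
    specimen_id: str = ""
    geometry: SpecimenGeometry | None = None

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, float)
        self.stress = np.asarray(self.stress, float)
        if self.strain.shape != self.stress.shape:
            raise ValueError("strain and stress must have equal length")
        if np.any(self.strain < 0) or np.any(self.strain >= 1):
            raise ValueError("engineering compression strain must lie in [0, 1)")

    @property
    def max_strain(self) -> float:
        return float(self.strain[-1])


@dataclass
class MechanicalSummary:
    """Per-specimen summary statistics of a reduced compression curve."""

    elastic_modulus: float
    strength_20: float | None
    stress_50: float | None
    fit_window: tuple[float, float]
    plastic_strain: float | None = None
    elastic_recovery: float | None = None
    condition: str = ""
    specimen_id: str = ""

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "specimen_id": self.specimen_id,
            "elastic_modulus_MPa": self.elastic_modulus,
            "strength_20_MPa": self.strength_20,
            "stress_50_MPa": self.stress_50,
            "fit_window": list(self.fit_window),
            "plastic_strain": self.plastic_strain,
            "elastic_recovery": self.elastic_recovery,
        }


@dataclass
class MeanCurve:
    """Pointwise mean stress over replicates with 95 % Student-t band."""

    strain: np.ndarray
    mean_stress: np.ndarray
    ci_halfwidth: np.ndarray
    n: int
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain": self.strain,
                "mean_stress_MPa": self.mean_stress,
                "ci95_halfwidth_MPa": self.ci_halfwidth,
                "n": self.n,
            }
        )


def to_stress_strain(
    curve: LoadDisplacementCurve, preload: float = PRELOAD_N
) -> StressStrainCurve:
    """Convert a load–displacement record to engineering stress–strain.

    σ_i = F_i / (π D0²/4) in MPa and ε_i = u_i / L0, order preserved.
    Samples recorded before the force first crosses the machine pre-load
    (default 1 N) are trimmed; pass ``preload=0`` to keep everything.
    """
    geom = curve.geometry
    u, f = curve.displacement, curve.force
    if preload > 0:
        above = np.nonzero(f >= preload)[0]
        if above.size:
            u, f = u[above[0]:], f[above[0]:]
    strain = u / geom.height
    if np.any(strain >= 1):
        raise ValueError("displacement reaches or exceeds the specimen height")
    stress = f / geom.area  # N / mm² = MPa
    return StressStrainCurve(
        strain=strain,
        stress=np.abs(stress),
        area=geom.area,
        height=geom.height,
        condition=curve.condition,
        specimen_id=curve.specimen_id,
        geometry=geom,
    )


def elastic_modulus(
    ssc: StressStrainCurve,
    window: tuple[float, float] | None = None,
    elastic_recovery: float | None = None,
    recovery_is_span: bool = True,
    min_points: int = 5,
) -> tuple[float, tuple[float, float]]:
    """Slope of the quasi-linear part of the curve, in MPa.

    The default window starts at 10 % strain (below which slanted samples
    load unevenly) and ends at 0.10 + elastic_recovery, i.e. the elastic
    strain span placed on top of the settling floor
    (``recovery_is_span=False`` instead uses the recovery as an absolute
    strain bound).  The modulus is the ordinary least-squares slope of σ
    over ε restricted to the window.
    """
    if window is None:
        if elastic_recovery is None:
            raise ValueError("provide either an explicit window or elastic_recovery")
        lo = 0.10
        hi = lo + elastic_recovery if recovery_is_span else elastic_recovery
        window = (lo, hi)
    lo, hi = window
    if not lo < hi:
        raise ValueError("fit window must satisfy lo < hi")
    mask = (ssc.strain >= lo) & (ssc.strain <= hi)
    if mask.sum() < min_points:
        raise ValueError(
            f"only {int(mask.sum())} samples inside window [{lo:.3g}, {hi:.3g}]; "
            f"need at least {min_points}"
        )
    slope, _ = np.polyfit(ssc.strain[mask], ssc.stress[mask], 1)
    return float(slope), (float(lo), float(hi))


def stress_at_strain(ssc: StressStrainCurve, target: float) -> float | None:
    """Linearly interpolated stress at strain ``target``.

    Returns None — an explicit absent value, never 0 — when the curve ends
    before the target strain.
    """
    if target < ssc.strain[0] or target > ssc.strain[-1]:
        return None
    return float(np.interp(target, ssc.strain, ssc.stress))


def compressive_strength(ssc: StressStrainCurve) -> float | None:
    """Compressive strength σ_st: the stress carried at 20 % strain."""
    return stress_at_strain(ssc, 0.20)


def recovery_split(
    curve: LoadDisplacementCurve, post_test_height: float | None = None
) -> tuple[float, float]:
    """Split the maximum strain into plastic and elastically recovered parts.

    plastic_strain = (L0 − post-test height)/L0; the elastic recovery is
    the rest of ε_max.  A post-test height below the minimum height reached
    during the test would imply negative recovery; it is clipped to zero
    with a warning.
    """
    geom = curve.geometry
    h_post = post_test_height if post_test_height is not None else geom.post_test_height
    if h_post is None:
        raise ValueError("post-test height not provided")
    if h_post > geom.height:
        raise ValueError("post-test height cannot exceed the initial height")
    eps_max = float(curve.displacement[-1] / geom.height)
    plastic = (geom.height - h_post) / geom.height
    recovery = eps_max - plastic
    if recovery < 0:
        warnings.warn(
            "post-test height below the minimum height reached during the "
            "test; clipping elastic recovery to 0",
            stacklevel=2,
        )
        recovery = 0.0
    return float(plastic), float(recovery)


def mean_curve(
    replicates: Sequence[StressStrainCurve],
    grid: np.ndarray | None = None,
    n_grid: int = 200,
    condition: str = "",
) -> MeanCurve:
    """Mean stress–strain curve over replicates with a 95 % CI band.

    Replicates are linearly interpolated onto a common strain grid that by
    default spans [0, min over replicates of max strain] uniformly, so every
    grid point is covered by every replicate.  The band is the two-sided
    Student-t 95 % interval of the pointwise mean.
    """
    if len(replicates) < 2:
        raise ValueError("confidence band needs at least 2 replicates")
    if grid is None:
        top = min(r.max_strain for r in replicates)
        grid = np.linspace(0.0, top, n_grid)
    grid = np.asarray(grid, float)
    stack = np.vstack([np.interp(grid, r.strain, r.stress) for r in replicates])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    tcrit = stats.t.ppf(0.975, df=n - 1)
    half = tcrit * sd / math.sqrt(n)
    return MeanCurve(
        strain=grid, mean_stress=mean, ci_halfwidth=half, n=n, condition=condition
    )


def summarize(
    curve: LoadDisplacementCurve,
    post_test_height: float | None = None,
    window: tuple[float, float] | None = None,
    preload: float = PRELOAD_N,
) -> MechanicalSummary:
    """Full DIN-50134-style reduction of one specimen record."""
    ssc = to_stress_strain(curve, preload=preload)
    plastic = recovery = None
    if post_test_height is not None or curve.geometry.post_test_height is not None:
        plastic, recovery = recovery_split(curve, post_test_height)
    if window is None and recovery is None:
        # no post-test measurement: fall back to a fixed foam-typical window
        window = (0.10, min(0.30, 0.95 * ssc.max_strain))
    m, win = elastic_modulus(ssc, window=window, elastic_recovery=recovery)
    return MechanicalSummary(
        elastic_modulus=m,
        strength_20=compressive_strength(ssc),
        stress_50=stress_at_strain(ssc, 0.50),
        fit_window=win,
        plastic_strain=plastic,
        elastic_recovery=recovery,
        condition=curve.condition,
        specimen_id=curve.specimen_id,
    )


def read_load_displacement(
    path: str | Path,
    geometry: SpecimenGeometry,
    displacement_col: str = "displacement_mm",
    force_col: str = "force_N",
    condition: str = "",
    specimen_id: str = "",
) -> LoadDisplacementCurve:
    """Read a delimited machine export (comma/semicolon/tab; decimal comma ok).

    The dialect is sniffed from the first lines.  Columns are looked up by
    name; a two-column headerless file is accepted as displacement, force.
    """
    path = Path(path)
    text = path.read_text()
    sep = _sniff_separator(text)
    df = pd.read_csv(io.StringIO(text), sep=sep, engine="python")
    if displacement_col not in df.columns or force_col not in df.columns:
        if df.shape[1] == 2:
            df = pd.read_csv(
                io.StringIO(text), sep=sep, engine="python", header=None,
                names=[displacement_col, force_col],
            )
        else:
            raise ValueError(
                f"{path}: columns {displacement_col!r}/{force_col!r} not found "
                f"in {list(df.columns)}"
            )
    u = _to_float(df[displacement_col])
    f = _to_float(df[force_col])
    return LoadDisplacementCurve(
        displacement=u,
        force=f,
        geometry=geometry,
        condition=condition,
        specimen_id=specimen_id or path.stem,
    )


def _sniff_separator(text: str) -> str:
    head = "\n".join(text.splitlines()[:5])
    counts = {sep: head.count(sep) for sep in ("\t", ";", ",")}
    # decimal commas masquerade as separators only when ';' or tab delimit
    if counts["\t"]:
        return "\t"
    if counts[";"]:
        return ";"
    return ","


def _to_float(col: pd.Series) -> np.ndarray:
    if col.dtype == object:
        col = col.astype(str).str.replace(",", ".", regex=False)
    return col.astype(float).to_numpy()
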