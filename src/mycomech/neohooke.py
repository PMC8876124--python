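"""Compressible Neo-Hookean constitutive model for foam-like composites.

The model describes the bulk response of mycelium-bound lignocellulosic
composites under large-strain uniaxial compression.  Its strain-energy
density in terms of principal stretches ``λ1, λ2, λ3`` is

    w = c (λ1² + λ2² + λ3² − 3 − 2 ln(λ1 λ2 λ3)) + d (λ1 λ2 λ3 − 1)²

with two stress-like parameters ``c`` (shear-like, μ = 2c) and ``d``
(volumetric, Lamé λ = 2d), both in MPa.  Requiring the lateral faces to be
stress free during uniaxial loading yields a closed-form axial second
Piola–Kirchhoff stress ``S33(λ)`` which is what gets fitted to measured
stress–strain curves.

Sign convention: the model layer is fully signed (λ < 1 and S33 < 0 in
compression).  Measured curves store |stress|; conversion happens exactly
once, inside :func:`fit_parameters`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import optimize

__all__ = [
    "NeoHookeParams",
    "UniaxialFit",
    "strain_energy",
    "lateral_solution",
    "uniaxial_stress",
    "brute_force_stress",
    "small_strain_moduli",
    "fit_parameters",
]

StressInterpretation = Literal["second_piola", "nominal"]


@dataclass(frozen=True)
class NeoHookeParams:
    """Constitutive parameter pair (c, d), both strictly positive, in MPa."""

    c: float
    d: float

    def __post_init__(self) -> None:
        if not (self.c > 0 and math.isfinite(self.c)):
            raise ValueError(f"c must be a positive finite stress, got {self.c}")
        if not (self.d > 0 and math.isfinite(self.d)):
            raise ValueError(f"d must be a positive finite stress, got {self.d}")

    def to_json(self) -> str:
        return json.dumps({"c_MPa": self.c, "d_MPa": self.d})

    @classmethod
    def from_json(cls, text: str) -> "NeoHookeParams":
        obj = json.loads(text)
        return cls(c=obj["c_MPa"], d=obj["d_MPa"])


@dataclass
class UniaxialFit:
    """Result of identifying (c, d) from a uniaxial stress–strain curve."""

    params: NeoHookeParams
    residual_norm: float
    strain_range: tuple[float, float]
    stress_interpretation: StressInterpretation
    success: bool
    n_points: int
    message: str = ""
    initial_guess: tuple[float, float] = field(default=(np.nan, np.nan))

    def to_dict(self) -> dict:
        return {
            "c_MPa": self.params.c,
            "d_MPa": self.params.d,
            "residual_norm": self.residual_norm,
            "strain_range": list(self.strain_range),
            "stress_interpretation": self.stress_interpretation,
            "success": self.success,
            "n_points": self.n_points,
            "message": self.message,
        }


def strain_energy(l1, l2, l3, params: NeoHookeParams):
    """Strain-energy density w(λ1, λ2, λ3) in MPa.

    Zero at the identity; non-negative for positive parameters.  Accepts
    scalars or broadcastable arrays of stretches.
    """
    l1, l2, l3 = np.asarray(l1, float), np.asarray(l2, float), np.asarray(l3, float)
    if np.any(l1 <= 0) or np.any(l2 <= 0) or np.any(l3 <= 0):
        raise ValueError("principal stretches must be strictly positive")
    J = l1 * l2 * l3
    iso = l1**2 + l2**2 + l3**2 - 3.0 - 2.0 * np.log(J)
    vol = (J - 1.0) ** 2
    return params.c * iso + params.d * vol


def lateral_solution(lam, params: NeoHookeParams, as_published: bool = False):
    """Volume ratio J(λ) and auxiliary ψ(λ) = 2 λ J for uniaxial loading.

    The lateral stress-free condition at λ1 = λ2 gives the quadratic

        d J² + (c/λ − d) J − c = 0,

    whose unique positive root is J.  Equivalently

        ψ(λ) = λ − c/d + sqrt(4 (c/d) λ² + (λ − c/d)²).

    ``as_published=True`` evaluates the variant with (λ + c/d)² under the
    root instead.  That form does not satisfy ψ(1) = 2 — and hence breaks
    the stress-free identity S33(1) = 0 — and is retained for comparison
    only; see docs/methods.md.

    Returns
    -------
    (J, psi) : floats or arrays matching the shape of ``lam``.
    """
    lam = np.asarray(lam, float)
    if np.any(lam <= 0):
        raise ValueError("axial stretch must be strictly positive")
    r = params.c / params.d
    if as_published:
        psi = lam - r + np.sqrt(4.0 * r * lam**2 + (lam + r) ** 2)
    else:
        psi = lam - r + np.sqrt(4.0 * r * lam**2 + (lam - r) ** 2)
    J = psi / (2.0 * lam)
    return J, psi


def uniaxial_stress(
    lam,
    params: NeoHookeParams,
    interpretation: StressInterpretation = "second_piola",
    as_published: bool = False,
):
    """Closed-form axial stress under laterally stress-free uniaxial loading.

        S33(λ) = 2c (1 − 1/λ²) + d (ψ/λ³) (ψ/(2λ) − 1)

    ``interpretation="second_piola"`` returns S33 (the quantity fitted to
    measured σ = F/A0 curves); ``"nominal"`` returns the first
    Piola–Kirchhoff stress P33 = λ S33, the actual force per reference area.
    Both are negative in compression (λ < 1).
    """
    lam = np.asarray(lam, float)
    if np.any(lam <= 0):
        raise ValueError("axial stretch must be strictly positive")
    _, psi = lateral_solution(lam, params, as_published=as_published)
    s33 = 2.0 * params.c * (1.0 - 1.0 / lam**2) + params.d * (psi / lam**3) * (
        psi / (2.0 * lam) - 1.0
    )
    if interpretation == "nominal":
        return lam * s33
    if interpretation == "second_piola":
        return s33
    raise ValueError(f"unknown stress interpretation: {interpretation!r}")


def brute_force_stress(lam: float, params: NeoHookeParams) -> float:
    """Independent uniaxial stress via direct energy minimization.

    Minimizes w(q, q, λ) over the lateral stretch q (bounded 1-D search),
    then evaluates S33 = (1/λ) ∂w/∂λ3 at the minimizer by central
    differences.  Slow by design — a verification oracle for
    :func:`uniaxial_stress`, not a production path.
    """
    lam = float(lam)
    if lam <= 0:
        raise ValueError("axial stretch must be strictly positive")

    def energy(q: float) -> float:
        return float(strain_energy(q, q, lam, params))

    res = optimize.minimize_scalar(
        energy, bounds=(1e-3, 10.0), method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise RuntimeError(f"lateral-stretch minimization failed: {res.message}")
    q = float(res.x)

    # polish: bisect the numerical energy gradient to pin the stationary
    # point far below the scalar minimizer's resolution
    def dw_dq(qv: float) -> float:
        hq = 1e-6 * qv
        return (energy(qv + hq) - energy(qv - hq)) / (2.0 * hq)

    lo, hi = q * (1.0 - 1e-3), q * (1.0 + 1e-3)
    widen = 0
    while dw_dq(lo) * dw_dq(hi) > 0 and widen < 20:
        lo *= 0.97
        hi *= 1.03
        widen += 1
    if dw_dq(lo) * dw_dq(hi) <= 0:
        q = float(optimize.brentq(dw_dq, lo, hi, xtol=1e-14, rtol=1e-15))
    # curvature guard: q must be a genuine minimum
    h = 1e-5 * max(q, 1.0)
    curv = (energy(q + h) - 2.0 * energy(q) + energy(q - h)) / h**2
    if curv <= 0:
        raise RuntimeError("energy not convex in lateral stretch at the minimizer")
    hl = 1e-6 * max(lam, 1.0)
    dw_dl3 = (
        float(strain_energy(q, q, lam + hl, params))
        - float(strain_energy(q, q, lam - hl, params))
    ) / (2.0 * hl)
    return dw_dl3 / lam


def small_strain_moduli(params: NeoHookeParams) -> tuple[float, float]:
    """Young's modulus E and Poisson ratio ν of the linearized model.

    Linearization about the identity gives shear modulus μ = 2c and first
    Lamé parameter 2d, hence

        E = 2c (2c + 3d) / (c + d),      ν = d / (2 (c + d)),

    with ν strictly inside (0, 1/2) for any positive pair.
    """
    c, d = params.c, params.d
    E = 2.0 * c * (2.0 * c + 3.0 * d) / (c + d)
    nu = d / (2.0 * (c + d))
    return E, nu


def _initial_guess(strain: np.ndarray, stress: np.ndarray) -> NeoHookeParams:
    """Start point from the secant modulus, inverted at ν0 = 0.25.

    At ν = 0.25 the moduli relations give c = d = E/5.
    """
    span = strain[-1] - strain[0]
    if span <= 0:
        raise ValueError("strain must span a positive range")
    m = (stress[-1] - stress[0]) / span
    m = abs(m)
    if m <= 0 or not math.isfinite(m):
        m = 0.1  # fall back to a foam-scale modulus
    g = max(m / 5.0, 1e-5)
    return NeoHookeParams(c=g, d=g)


def fit_parameters(
    strain,
    stress,
    interpretation: StressInterpretation = "second_piola",
    strain_range: tuple[float, float] | None = None,
    bounds: tuple[float, float] = (1e-6, 1e3),
    x0: NeoHookeParams | None = None,
) -> UniaxialFit:
    """Identify (c, d) from a measured compression curve by least squares.

    Parameters
    ----------
    strain, stress:
        Engineering compression strain ε (monotone non-decreasing,
        0 ≤ ε < 1) and stress magnitude |σ| in MPa, e.g. from a per-condition
        mean curve.  Mapped to stretch by λ = 1 − ε.
    interpretation:
        ``"second_piola"`` compares |S33(λ)| with σ (the convention used
        when fitting S33 directly to F/A0); ``"nominal"`` compares
        |λ S33(λ)| with σ, the mechanically exact match for force per
        undeformed area.
    strain_range:
        Optional (ε_lo, ε_hi) window restricting the fit.
    bounds:
        Box for both parameters, enforced by optimizing log c, log d.

    The optimization is deterministic bounded least squares on
    log-parameters started from the small-strain modulus inverted at
    ν₀ = 1/4.
    """
    strain = np.asarray(strain, float)
    stress = np.asarray(stress, float)
    if strain.shape != stress.shape or strain.ndim != 1:
        raise ValueError("strain and stress must be equal-length 1-D arrays")
    if np.any(np.diff(strain) < 0):
        raise ValueError("strain must be monotone non-decreasing")
    if np.any(strain < 0) or np.any(strain >= 1):
        raise ValueError("compression strain must lie in [0, 1)")
    mask = np.ones(strain.size, bool)
    if strain_range is not None:
        lo, hi = strain_range
        mask = (strain >= lo) & (strain <= hi)
    eps = strain[mask]
    sig = np.abs(stress[mask])
    if eps.size < 5:
        raise ValueError("need at least 5 samples inside the fit window")
    if eps[-1] - eps[0] < 0.05:
        raise ValueError("fit window must span at least 5% strain")
    if np.all(sig == 0):
        raise ValueError("all-zero stress curve cannot identify parameters")

    lam = 1.0 - eps
    guess = x0 or _initial_guess(eps, sig)
    lo_b, hi_b = math.log(bounds[0]), math.log(bounds[1])

    def residuals(logp: np.ndarray) -> np.ndarray:
        p = NeoHookeParams(c=math.exp(logp[0]), d=math.exp(logp[1]))
        model = np.abs(uniaxial_stress(lam, p, interpretation=interpretation))
        return model - sig

    start = np.clip(
        [math.log(guess.c), math.log(guess.d)], lo_b + 1e-9, hi_b - 1e-9
    )
    res = optimize.least_squares(
        residuals,
        start,
        bounds=([lo_b, lo_b], [hi_b, hi_b]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    params = NeoHookeParams(c=math.exp(res.x[0]), d=math.exp(res.x[1]))
    return UniaxialFit(
        params=params,
        residual_norm=float(np.linalg.norm(res.fun)),
        strain_range=(float(eps[0]), float(eps[-1])),
        stress_interpretation=interpretation,
        success=bool(res.success),
        n_points=int(eps.size),
        message=str(res.message),
        initial_guess=(guess.c, guess.d),
    )
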