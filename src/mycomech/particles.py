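"""Substrate particle analytics: Feret diameters, sieve fractions, density.

Milled lignocellulosic substrates (hemp shives, rapeseed straw) are
classified into size fractions on square-mesh sieves and characterized by
image analysis.  This module computes, from 2-D particle outlines:

* min/max Feret diameters (rotating-calipers on the convex hull) and their
  ratio, the standard elongation descriptor;
* ratio histograms with a modal value per population;
* sieve mass fractions, a particle passing a mesh iff its minimum Feret
  diameter is below the mesh size (the usual proxy for square-mesh sieving
  of elongated particles);
* bulk density from total mass and bulk volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "ParticleOutline",
    "SieveSpec",
    "FeretSummary",
    "feret_diameters",
    "ratio_histogram",
    "sieve_classify",
    "bulk_density",
    "DEFAULT_SIEVE",
]


@dataclass
class ParticleOutline:
    """A simple polygon outline (mm) with a mass proxy.

    When no mass is supplied, area × 1 mm thickness serves as the proxy
    (mass fractions are insensitive to the common density factor).
    """

    vertices: np.ndarray
    mass: float | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if self.vertices.shape[0] < 3:
            raise ValueError("polygon needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ValueError("polygon is self-intersecting or otherwise invalid")
        if poly.area <= 0:
            raise ValueError("polygon must have positive area")
        if self.mass is not None and self.mass <= 0:
            raise ValueError("supplied mass must be positive")

    @property
    def area(self) -> float:
        return Polygon(self.vertices).area

    @property
    def mass_proxy(self) -> float:
        return self.mass if self.mass is not None else self.area  # × 1 mm


@dataclass(frozen=True)
class SieveSpec:
    """Ascending mesh sizes (mm) defining fraction intervals.

    The three-deck sizer of the lab study uses 0.63, 2 and 3.15 mm meshes,
    giving fractions small (0.63–2), medium (2–3.15) and large (> 3.15).
    """

    meshes: tuple[float, ...] = (0.63, 2.0, 3.15)
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.meshes) < 1:
            raise ValueError("need at least one mesh size")
        if any(b <= a for a, b in zip(self.meshes, self.meshes[1:])):
            raise ValueError("mesh sizes must be strictly ascending")

    @property
    def fraction_labels(self) -> tuple[str, ...]:
        """Interval labels: undersize, between-mesh fractions, oversize."""
        if self.labels is not None:
            if len(self.labels) != len(self.meshes) + 1:
                raise ValueError("need len(meshes)+1 labels")
            return self.labels
        labels = [f"<{self.meshes[0]:g}mm"]
        labels += [
            f"{a:g}-{b:g}mm" for a, b in zip(self.meshes, self.meshes[1:])
        ]
        labels.append(f">{self.meshes[-1]:g}mm")
        return tuple(labels)


DEFAULT_SIEVE = SieveSpec()


@dataclass
class FeretSummary:
    """Per-particle Feret data plus a ratio histogram for one population."""

    min_feret: np.ndarray
    max_feret: np.ndarray
    ratio: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    modal_ratio: float

    @property
    def n(self) -> int:
        return int(self.ratio.size)


def _hull_vertices(outline: ParticleOutline | np.ndarray) -> np.ndarray:
    pts = outline.vertices if isinstance(outline, ParticleOutline) else np.asarray(
        outline, float
    )
    hull = Polygon(pts).convex_hull
    if hull.geom_type != "Polygon":  # degenerate: all points collinear
        raise ValueError("degenerate (collinear) outline has no Feret ratio")
    return np.asarray(hull.exterior.coords)[:-1]


def feret_diameters(outline: ParticleOutline | np.ndarray) -> tuple[float, float]:
    """(min, max) Feret diameters of a particle outline.

    The maximum Feret diameter is the largest pairwise distance between
    convex-hull vertices; the minimum is the smallest projection width over
    hull-edge normal directions (rotating calipers: the minimum width is
    always attained flush against a hull edge).
    """
    hull = _hull_vertices(outline)
    diffs = hull[:, None, :] - hull[None, :, :]
    dmax = float(np.sqrt((diffs**2).sum(-1)).max())
    edges = np.roll(hull, -1, axis=0) - hull
    lengths = np.linalg.norm(edges, axis=1)
    keep = lengths > 0
    directions = edges[keep] / lengths[keep, None]
    # width perpendicular to each edge direction
    normals = np.column_stack([-directions[:, 1], directions[:, 0]])
    proj = hull @ normals.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    dmin = float(widths.min())
    return dmin, dmax


def ratio_histogram(
    particles: Sequence[ParticleOutline | np.ndarray],
    bins: int | np.ndarray = 20,
) -> FeretSummary:
    """Histogram of min/max Feret ratios over a particle population.

    Default: 20 uniform bins on (0, 1].  The modal ratio is the midpoint of
    the highest-count bin (ties resolved toward the lower bin).
    """
    if len(particles) == 0:
        raise ValueError("empty particle population")
    ferets = np.array([feret_diameters(p) for p in particles])
    ratio = ferets[:, 0] / ferets[:, 1]
    edges = (
        np.linspace(0.0, 1.0, bins + 1) if np.isscalar(bins) else np.asarray(bins, float)
    )
    counts, edges = np.histogram(ratio, bins=edges)
    imode = int(np.argmax(counts))  # argmax takes the first (lower) maximum
    modal = 0.5 * (edges[imode] + edges[imode + 1])
    return FeretSummary(
        min_feret=ferets[:, 0],
        max_feret=ferets[:, 1],
        ratio=ratio,
        bin_edges=edges,
        counts=counts,
        modal_ratio=float(modal),
    )


def sieve_classify(
    particles: Sequence[ParticleOutline],
    sieve: SieveSpec = DEFAULT_SIEVE,
) -> dict[str, float]:
    """Mass fraction per sieve interval; fractions sum to 1 exactly.

    A particle passes a mesh iff its minimum Feret diameter is strictly
    below the mesh size; it lands in the interval between the largest mesh
    it does not pass and the smallest it passes.  Buckets below the finest
    mesh (undersize) and above the coarsest (oversize) are included.
    """
    if len(particles) == 0:
        raise ValueError("empty particle population")
    labels = sieve.fraction_labels
    masses = np.zeros(len(labels))
    for p in particles:
        m = p.mass_proxy
        if m <= 0:
            raise ValueError("non-positive particle mass")
        dmin, _ = feret_diameters(p)
        # strictly-below passage: a particle exactly at a mesh size stays on it
        idx = int(np.searchsorted(np.asarray(sieve.meshes), dmin, side="right"))
        masses[idx] += m
    total = masses.sum()
    return {label: float(m / total) for label, m in zip(labels, masses)}


def bulk_density(total_mass_g: float, bulk_volume_cm3: float) -> float:
    """Bulk density in g/cm³ from total mass and poured bulk volume."""
    if total_mass_g <= 0:
        raise ValueError("total mass must be positive")
    if bulk_volume_cm3 <= 0:
        raise ValueError("bulk volume must be positive")
    return total_mass_g / bulk_volume_cm3
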