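"""Geometry of face pairs in a statistical face space.

A statistical face space places every face at a point in a D-dimensional
latent space whose origin is the average face and whose coordinates are
measured in standard deviations of the generating population (D = 398 for a
morphable model with 199 shape and 199 texture components).  The relation of
a face *pair* to the origin is fully captured by three numbers: the radial
lengths ``r1`` and ``r2`` of the two face vectors and the angle ``theta``
between them.  The Euclidean distance between the faces follows from the law
of cosines,

    d = sqrt(r1**2 + r2**2 - 2*r1*r2*cos(theta)),

so a grid over (r1, r2, theta) induces a grid over distances while also
dissociating distance from position relative to the origin.

This module enumerates such geometric designs, constructs latent vector
pairs that realize a given (r1, r2, theta) exactly with uniformly random
orientation, and provides the two distance metrics (Euclidean and cosine)
used by the candidate dissimilarity models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_DIM",
    "PairGeometry",
    "GeometricDesign",
    "LatentVector",
    "FacePairStimulus",
    "enumerate_design",
    "expected_design_size",
    "sample_pair",
    "pair_geometry_of",
    "euclidean_distance",
    "cosine_distance",
    "normalize_distances",
    "design_distances",
]

#: Latent dimensionality of the default statistical face space
#: (199 shape + 199 texture components).
DEFAULT_DIM = 398

#: Number of latent dimensions conventionally labeled "shape" (the first
#: half of the coordinate vector); the remainder are "texture".
SHAPE_DIMS = 199


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PairGeometry:
    """The triple (r1, r2, theta) relating a face pair to the origin.

    Radii are in face-space SD units and must be nonnegative; the angle is
    in degrees in [0, 180].  The canonical form stores ``r1 <= r2`` and
    collapses the angle to 0 whenever a radius is 0 (the angle of a zero
    vector is undefined).
    """

    r1: float
    r2: float
    theta_deg: float

    def __post_init__(self):
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError(f"radii must be nonnegative, got ({self.r1}, {self.r2})")
        if not (0.0 <= self.theta_deg <= 180.0):
            raise ValueError(f"theta_deg must lie in [0, 180], got {self.theta_deg}")

    @classmethod
    def canonical(cls, r1: float, r2: float, theta_deg: float) -> "PairGeometry":
        """Build the canonical representative: r1 <= r2, zero-radius angle 0."""
        a, b = sorted((float(r1), float(r2)))
        theta = 0.0 if a == 0.0 else float(theta_deg)
        return cls(a, b, theta)

    @property
    def euclidean(self) -> float:
        """Distance between the two faces, by the law of cosines."""
        t = np.radians(self.theta_deg)
        sq = self.r1**2 + self.r2**2 - 2.0 * self.r1 * self.r2 * np.cos(t)
        return float(np.sqrt(max(sq, 0.0)))

    def key(self) -> tuple:
        return (self.r1, self.r2, self.theta_deg)


@dataclass(frozen=True)
class GeometricDesign:
    """An ordered, deduplicated list of pair geometries with their grids."""

    pairs: tuple
    radius_grid: tuple
    angle_grid: tuple

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def pair_ids(self) -> np.ndarray:
        return np.arange(len(self.pairs))

    def to_frame(self, set_label: str = "A") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_id": self.pair_ids,
                "r1": [g.r1 for g in self.pairs],
                "r2": [g.r2 for g in self.pairs],
                "theta_deg": [g.theta_deg for g in self.pairs],
                "set_label": set_label,
            }
        )


def _validated_grids(radius_grid, angle_grid):
    radii = np.asarray(list(radius_grid), dtype=float)
    angles = np.asarray(list(angle_grid), dtype=float)
    if radii.size == 0 or angles.size == 0:
        raise ValueError("radius and angle grids must be nonempty")
    if np.any(radii < 0):
        raise ValueError("radii must be nonnegative")
    if np.any((angles < 0) | (angles > 180)):
        raise ValueError("angles must lie in [0, 180] degrees")
    return np.unique(radii), np.unique(angles)


def enumerate_design(radius_grid: Iterable[float], angle_grid: Iterable[float]) -> GeometricDesign:
    """Enumerate all unique pair geometries on a radius x angle grid.

    All unordered pairs of nonzero radii are crossed with every angle; if the
    grid contains the zero radius, one additional entry per radius value
    pairs it with the origin (with the angle collapsed to 0).  Duplicates
    under canonicalization (radius exchange, zero-radius angle collapse) are
    removed.  With k nonzero radii, zero on the grid, and m angles the count
    is ``m*k*(k+1)/2 + (k+1)``; the default 8x8 grid yields 232 pairs.
    """
    radii, angles = _validated_grids(radius_grid, angle_grid)
    nonzero = radii[radii > 0]
    seen: dict = {}
    for i, r1 in enumerate(nonzero):
        for r2 in nonzero[i:]:
            for a in angles:
                g = PairGeometry.canonical(r1, r2, a)
                seen.setdefault(g.key(), g)
    if 0.0 in radii:
        for r in radii:
            g = PairGeometry.canonical(0.0, r, 0.0)
            seen.setdefault(g.key(), g)
    return GeometricDesign(tuple(seen.values()), tuple(radii), tuple(angles))


def expected_design_size(radius_grid: Iterable[float], angle_grid: Iterable[float]) -> int:
    """Closed-form design size: m*k*(k+1)/2 nonzero-radius pairs plus, if the
    grid contains zero, one origin pair per radius value (k+1 entries)."""
    radii, angles = _validated_grids(radius_grid, angle_grid)
    k = int(np.sum(radii > 0))
    m = int(angles.size)
    n = m * k * (k + 1) // 2
    if 0.0 in radii:
        n += k + 1
    return n


@dataclass
class LatentVector:
    """A point in the D-dimensional face space (units: population SDs).

    The first half of the coordinates is labeled "shape" and the second half
    "texture", mirroring the 199/199 split of the morphable model.
    """

    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 1:
            raise ValueError("latent coordinates must be a 1-D vector")

    @property
    def dim(self) -> int:
        return self.coords.size

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.coords))

    @property
    def shape_part(self) -> np.ndarray:
        return self.coords[: self.dim // 2]

    @property
    def texture_part(self) -> np.ndarray:
        return self.coords[self.dim // 2 :]


@dataclass
class FacePairStimulus:
    """A realized face pair: geometry plus the two latent vectors."""

    pair_id: int
    geometry: PairGeometry
    v1: LatentVector
    v2: LatentVector
    set_label: str = "A"


def _coords(v) -> np.ndarray:
    return v.coords if isinstance(v, LatentVector) else np.asarray(v, dtype=float)


def sample_pair(geometry: PairGeometry, dim: int = DEFAULT_DIM, seed=None):
    """Sample two latent vectors realizing ``geometry`` exactly.

    A uniformly random orthonormal 2-frame (e1, e2) is built by Gram-Schmidt
    on two independent standard-normal draws (redrawing on numerical
    collinearity); then v1 = r1*e1 and v2 = r2*(cos(theta)*e1 +
    sin(theta)*e2).  Norms and the mutual angle are exact to floating-point
    precision, and the pair's orientation is uniform on the sphere.
    """
    if dim < 2:
        raise ValueError("dim must be at least 2")
    rng = _as_rng(seed)
    while True:
        a, b = rng.standard_normal((2, dim))
        na = np.linalg.norm(a)
        if na < 1e-12:
            continue
        e1 = a / na
        resid = b - (b @ e1) * e1
        nr = np.linalg.norm(resid)
        if nr < 1e-12:
            continue
        e2 = resid / nr
        break
    t = np.radians(geometry.theta_deg)
    v1 = geometry.r1 * e1
    v2 = geometry.r2 * (np.cos(t) * e1 + np.sin(t) * e2)
    return LatentVector(v1), LatentVector(v2)


def pair_geometry_of(v1, v2) -> PairGeometry:
    """Recover (r1, r2, theta) from two latent vectors.

    The angle is the arccosine of the normalized inner product (argument
    clipped to [-1, 1]) and is reported as 0 when either norm is zero.
    """
    x, y = _coords(v1), _coords(v2)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    n1, n2 = float(np.linalg.norm(x)), float(np.linalg.norm(y))
    if n1 == 0.0 or n2 == 0.0:
        theta = 0.0
    else:
        c = np.clip((x @ y) / (n1 * n2), -1.0, 1.0)
        theta = float(np.degrees(np.arccos(c)))
    return PairGeometry(n1, n2, theta)


def euclidean_distance(v1, v2) -> float:
    x, y = _coords(v1), _coords(v2)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(np.linalg.norm(x - y))


def cosine_distance(v1, v2) -> float:
    """Cosine distance 1 - cos(theta); undefined (error) for zero vectors."""
    x, y = _coords(v1), _coords(v2)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    n1, n2 = np.linalg.norm(x), np.linalg.norm(y)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("cosine distance is undefined for a zero vector")
    return float(1.0 - np.clip((x @ y) / (n1 * n2), -1.0, 1.0))


def normalize_distances(d) -> np.ndarray:
    """Divide distances by the within-set maximum, mapping them onto [0, 1]."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    m = d.max(initial=0.0)
    if m <= 0:
        raise ValueError("cannot normalize an all-zero distance set")
    return d / m


def design_distances(design: GeometricDesign) -> np.ndarray:
    """Per-pair Euclidean distances implied by the design's geometry alone."""
    return np.array([g.euclidean for g in design])
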