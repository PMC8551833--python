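"""Reduced mechanical model of passive left-ventricular inflation.

The ventricular wall is idealised as an incompressible, thick-walled spherical
shell made of a Fung/Guccione-type exponential material with circumferential
fibres.  Under an internal (intra-ventricular) pressure ``p`` the deformation
is spherically symmetric: a reference radius ``R`` maps to

    r(R) = (R**3 + a**3 - A**3) ** (1/3),

where ``A`` is the reference endocardial radius and ``a`` the inflated one, so
volume is conserved exactly across the wall.  The inner radius ``a`` is found
by integrating the radial equilibrium equation across the wall and solving for
the load balance with the cavity pressure.

This closed-form kinematic family keeps every feature that the inverse
estimators rely on - the constitutive parameter dependence of the energy,
a monotone pressure response, distinct endocardial/epicardial surfaces and
fully three-dimensional displacement fields - while being solvable in
milliseconds with verifiable incompressibility and virtual-work oracles.

Units are millimetres and kilopascals throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MaterialParams",
    "GeometryParams",
    "GreenStrain",
    "DisplacementField",
    "Surface",
    "PRESSURE_RANGE",
    "C1_RANGE",
    "C2_RANGE",
    "N_WALL_POINTS",
    "N_OBSERVED_SURFACE",
    "N_PREDICTED_SURFACE",
    "strain_energy",
    "cavity_pressure",
    "inflate",
    "displacement_field",
    "total_strain_energy",
    "virtual_work_pressure",
    "sample_wall_points",
    "sample_surface",
    "loaded_surface",
    "make_pressure_trace",
]

#: Training / physiological ranges of the estimated surrogate inputs.
PRESSURE_RANGE = (0.15, 1.5)   # kPa, diastasis to end-diastole
C1_RANGE = (2.0, 5.0)          # kPa, overall stiffness scale
C2_RANGE = (4.0, 40.0)         # dimensionless fibre exponent

#: Default observation discretisation (points across the wall, points per
#: observed dense surface, points per predicted sparse surface).
N_WALL_POINTS = 1109
N_OBSERVED_SURFACE = 7579
N_PREDICTED_SURFACE = 1072

_GL_X, _GL_W = np.polynomial.legendre.leggauss(64)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


class SolverError(RuntimeError):
    """Raised when the inflation boundary-value problem cannot be solved."""


@dataclass(frozen=True)
class MaterialParams:
    """Constitutive parameters of the exponential strain-energy law.

    ``c1`` (kPa) scales the overall stiffness; ``c2``, ``c3`` and ``c4``
    are the dimensionless exponents acting on fibre, cross-fibre/radial and
    shear strain terms.  ``c3`` and ``c4`` have low identifiability from
    macro-scale kinematics and are held fixed at their defaults.
    """

    c1: float = 3.5
    c2: float = 22.0
    c3: float = 3.67
    c4: float = 25.77

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3", "c4"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class GeometryParams:
    """Reference (diastasis) shell geometry, mm.

    The default wall thickness is deliberately thin (0.75 mm): a closed
    spherical wall has no bending compliance and is structurally far stiffer
    than a ventricle, so the thickness is calibrated to reproduce the
    pressure-displacement compliance of diastolic filling (wall displacements
    of roughly 0.5-10 mm and fibre strains up to ~0.5 over the physiological
    parameter ranges) rather than the anatomical wall thickness.
    """

    inner_radius: float = 25.0
    outer_radius: float = 25.75

    def __post_init__(self) -> None:
        if not (0.0 < self.inner_radius < self.outer_radius):
            raise ValueError(
                "require 0 < inner_radius < outer_radius, got "
                f"{self.inner_radius}, {self.outer_radius}"
            )


@dataclass(frozen=True)
class GreenStrain:
    """Green-Lagrange strain components in the fibre (f), cross-fibre (c)
    and radial (r) material axes."""

    e_ff: float = 0.0
    e_cc: float = 0.0
    e_rr: float = 0.0
    e_fc: float = 0.0
    e_fr: float = 0.0
    e_cr: float = 0.0


@dataclass
class DisplacementField:
    """Material points (n, 3) paired index-wise with displacement vectors (n, 3)."""

    points: np.ndarray
    vectors: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.points.shape != self.vectors.shape or self.points.ndim != 2 \
                or self.points.shape[1] != 3:
            raise ValueError("points and vectors must both have shape (n, 3)")
        if not (np.isfinite(self.points).all() and np.isfinite(self.vectors).all()):
            raise ValueError("non-finite entries in displacement field")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Surface:
    """A labelled point set describing one ventricular surface at one time."""

    label: str                      # "endo" | "epi"
    points: np.ndarray              # (n, 3) mm
    time_tag: str = "reference"     # "reference" | "loaded"

    def __post_init__(self) -> None:
        if self.label not in ("endo", "epi"):
            raise ValueError(f"label must be 'endo' or 'epi', got {self.label!r}")
        if self.time_tag not in ("reference", "loaded"):
            raise ValueError(f"time_tag must be 'reference' or 'loaded', got {self.time_tag!r}")
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) == 0:
            raise ValueError("points must be a non-empty (n, 3) array")
        if not np.isfinite(self.points).all():
            raise ValueError("non-finite surface points")

    def __len__(self) -> int:
        return len(self.points)


def strain_energy(strain: GreenStrain, material: MaterialParams) -> float:
    """Strain-energy density (kPa) of the exponential constitutive law.

    ``psi = c1/2 * (exp(Q) - 1)`` with
    ``Q = c2*Eff^2 + c3*(Ecc^2 + Err^2 + Ecr^2) + 2*c4*(Efc^2 + Efr^2)``.
    """
    comps = np.array([strain.e_ff, strain.e_cc, strain.e_rr,
                      strain.e_fc, strain.e_fr, strain.e_cr], dtype=float)
    if not np.isfinite(comps).all():
        raise ValueError("non-finite strain components")
    q = (material.c2 * strain.e_ff ** 2
         + material.c3 * (strain.e_cc ** 2 + strain.e_rr ** 2 + strain.e_cr ** 2)
         + 2.0 * material.c4 * (strain.e_fc ** 2 + strain.e_fr ** 2))
    return 0.5 * material.c1 * float(np.expm1(q))


def _dW_dlambda(lam: np.ndarray, material: MaterialParams) -> np.ndarray:
    # Energy along the spherically symmetric path, as a function of the
    # tangential stretch lam (radial stretch lam**-2).  Fibre strain equals
    # cross-fibre strain here, so c2 and c3 both act on the tangential term.
    e_t = 0.5 * (lam ** 2 - 1.0)
    e_r = 0.5 * (lam ** -4 - 1.0)
    q = (material.c2 + material.c3) * e_t ** 2 + material.c3 * e_r ** 2
    dq = (2.0 * (material.c2 + material.c3) * e_t * lam
          - 4.0 * material.c3 * e_r * lam ** -5)
    return 0.5 * material.c1 * np.exp(q) * dq


def cavity_pressure(geometry: GeometryParams, material: MaterialParams,
                    inner_radius: float) -> float:
    """Pressure (kPa) required to hold the shell at inflated inner radius ``a``.

    Integrates the radial equilibrium equation
    ``d(sigma_rr)/dr = 2 (sigma_tt - sigma_rr) / r`` across the deformed wall
    with a traction-free outer surface, using the incompressible kinematics
    and ``sigma_tt - sigma_rr = lam * W'(lam) / 2``.
    """
    a = float(inner_radius)
    A, B = geometry.inner_radius, geometry.outer_radius
    if a < A - 1e-12:
        raise ValueError(f"inflated inner radius {a} below reference {A}")
    k = a ** 3 - A ** 3
    b = (B ** 3 + k) ** (1.0 / 3.0)
    r = a + (b - a) * _GL_X
    R = (r ** 3 - k) ** (1.0 / 3.0)
    lam = r / R
    integrand = lam * _dW_dlambda(lam, material) / r
    return float((b - a) * np.sum(_GL_W * integrand))


def inflate(geometry: GeometryParams, material: MaterialParams, p: float) -> float:
    """Solve the inflation problem: inner radius ``a`` (mm) at pressure ``p`` (kPa)."""
    if not np.isfinite(p) or p < 0:
        raise ValueError(f"pressure must be finite and >= 0, got {p!r}")
    A = geometry.inner_radius
    if p == 0.0:
        return A
    hi = 1.05 * A
    for _ in range(80):
        if cavity_pressure(geometry, material, hi) >= p:
            break
        hi = A + 2.0 * (hi - A)
    else:
        raise SolverError(
            f"no inflation bracket found for p={p} kPa with {material} {geometry}")
    return float(brentq(
        lambda a: cavity_pressure(geometry, material, a) - p,
        A, hi, xtol=1e-10, rtol=1e-12, maxiter=200))


def displacement_field(geometry: GeometryParams, material: MaterialParams,
                       p: float, points: np.ndarray) -> DisplacementField:
    """Displacement vectors of wall material ``points`` under pressure ``p``.

    The field is purely radial: ``u(x) = (r(R)/R - 1) x`` with ``R = |x|``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    R = np.linalg.norm(pts, axis=1)
    A, B = geometry.inner_radius, geometry.outer_radius
    tol = 1e-9 * B
    if np.any(R < A - tol) or np.any(R > B + tol):
        raise ValueError("material points must lie within the wall [A, B]")
    a = inflate(geometry, material, p)
    k = a ** 3 - A ** 3
    r = (R ** 3 + k) ** (1.0 / 3.0)
    u = ((r / R) - 1.0)[:, None] * pts
    return DisplacementField(points=pts, vectors=u)


def total_strain_energy(geometry: GeometryParams, material: MaterialParams,
                        inner_radius: float) -> float:
    """Total stored energy (kPa*mm^3) of the shell inflated to inner radius ``a``."""
    A, B = geometry.inner_radius, geometry.outer_radius
    k = float(inner_radius) ** 3 - A ** 3
    R = A + (B - A) * _GL_X
    lam = (R ** 3 + k) ** (1.0 / 3.0) / R
    e_t = 0.5 * (lam ** 2 - 1.0)
    e_r = 0.5 * (lam ** -4 - 1.0)
    q = (material.c2 + material.c3) * e_t ** 2 + material.c3 * e_r ** 2
    psi = 0.5 * material.c1 * np.expm1(q)
    return float((B - A) * np.sum(_GL_W * psi * 4.0 * np.pi * R ** 2))


def virtual_work_pressure(geometry: GeometryParams, material: MaterialParams,
                          inner_radius: float, step: float = 1e-4) -> float:
    """Virtual-work estimate of the cavity pressure at inflated radius ``a``.

    Central difference of total stored energy with respect to cavity volume
    along the incompressible kinematic family; an independent oracle for
    :func:`cavity_pressure`.
    """
    a = float(inner_radius)
    da = step * geometry.inner_radius
    u_hi = total_strain_energy(geometry, material, a + da)
    u_lo = total_strain_energy(geometry, material, a - da)
    v_hi = 4.0 / 3.0 * np.pi * (a + da) ** 3
    v_lo = 4.0 / 3.0 * np.pi * (a - da) ** 3
    return (u_hi - u_lo) / (v_hi - v_lo)


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sample_wall_points(geometry: GeometryParams, n: int = N_WALL_POINTS,
                       seed: int | None = 0) -> np.ndarray:
    """Seeded, approximately uniform sample of ``n`` points of the wall volume."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    A3, B3 = geometry.inner_radius ** 3, geometry.outer_radius ** 3
    radii = (A3 + rng.random(n) * (B3 - A3)) ** (1.0 / 3.0)
    return radii[:, None] * _unit_vectors(rng, n)


def _fibonacci_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform unit-sphere lattice (golden-angle spiral) under a seeded
    random rotation, so distinct seeds give distinct but equally uniform
    samples."""
    i = np.arange(n) + 0.5
    polar = np.arccos(1.0 - 2.0 * i / n)
    azimuth = np.pi * (1.0 + np.sqrt(5.0)) * i
    pts = np.column_stack([np.sin(polar) * np.cos(azimuth),
                           np.sin(polar) * np.sin(azimuth),
                           np.cos(polar)])
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return pts @ q.T


def sample_surface(geometry: GeometryParams, label: str,
                   n: int = N_OBSERVED_SURFACE, seed: int | None = 0,
                   time_tag: str = "reference") -> Surface:
    """Seeded quasi-uniform sample of the endo- or epicardial sphere.

    Points form a Fibonacci lattice under a seeded random rotation; the
    lattice keeps the point spacing nearly constant, which minimises the
    discretisation floor of the contour-matching distance.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if label not in ("endo", "epi"):
        raise ValueError(f"label must be 'endo' or 'epi', got {label!r}")
    rng = np.random.default_rng(seed)
    radius = geometry.inner_radius if label == "endo" else geometry.outer_radius
    return Surface(label=label, time_tag=time_tag,
                   points=radius * _fibonacci_sphere(n, rng))


def loaded_surface(geometry: GeometryParams, material: MaterialParams,
                   p: float, reference: Surface) -> Surface:
    """Displace a reference surface to its loaded configuration at pressure ``p``."""
    disp = displacement_field(geometry, material, p, reference.points)
    return Surface(label=reference.label, time_tag="loaded",
                   points=reference.points + disp.vectors)


def make_pressure_trace(p_max: float, n_frames: int = 10,
                        p_min: float = PRESSURE_RANGE[0]) -> np.ndarray:
    """Monotone linear pressure trace (kPa) from ``p_min`` to ``p_max``."""
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if not (p_min < p_max):
        raise ValueError("require p_min < p_max")
    lo, hi = PRESSURE_RANGE
    if p_max > hi + 1e-12 or p_min < lo - 1e-12:
        warnings.warn(
            f"pressure trace [{p_min}, {p_max}] extends outside the training "
            f"range [{lo}, {hi}] kPa", stacklevel=2)
    return np.linspace(p_min, p_max, n_frames)
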