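"""Zernike representation of the anterior corneal surface.

Elevation maps (heights in μm on a rectangular mm grid) are decomposed into
Zernike polynomials using the ANSI/OSA double-index convention with
unit-variance (RMS) normalization: the Euclidean norm of a coefficient
vector equals the RMS of the reconstructed surface over the pupil, which is
what makes the clinical aberration groups (total, HOA, astigmatism,
coma-like, spherical-like) plain sums of squares.

The 7th-order expansion used throughout has (7+1)(7+2)/2 = 36 terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
from numpy.polynomial.legendre import leggauss

__all__ = [
    "ElevationMap",
    "ZernikeCoefficients",
    "RmsGroups",
    "FitError",
    "n_terms",
    "osa_index",
    "index_to_nm",
    "zernike_term",
    "zernike_basis",
    "fit_elevation",
    "reconstruct",
    "rescale_pupil",
    "elevation_to_wavefront",
    "rms_groups",
]

#: refractive index step across the air/tear-stroma interface used to turn a
#: surface height difference into optical path difference.
DEFAULT_DELTA_N = 0.376


class FitError(ValueError):
    """Raised when an elevation map cannot support the requested fit."""


# ---------------------------------------------------------------------------
# indexing helpers (ANSI/OSA single index j = (n(n+2)+m)/2)
# ---------------------------------------------------------------------------

def n_terms(max_order: int) -> int:
    """Number of Zernike terms through radial order ``max_order``."""
    return (max_order + 1) * (max_order + 2) // 2


def osa_index(n: int, m: int) -> int:
    """ANSI/OSA single index for radial order n, azimuthal frequency m."""
    _check_nm(n, m)
    return (n * (n + 2) + m) // 2


def index_to_nm(j: int) -> tuple[int, int]:
    """Inverse of :func:`osa_index`."""
    if j < 0:
        raise ValueError(f"index must be non-negative, got {j}")
    n = int(math.ceil((-3.0 + math.sqrt(9.0 + 8.0 * j)) / 2.0))
    m = 2 * j - n * (n + 2)
    return n, m


def _check_nm(n: int, m: int) -> None:
    if n < 0 or abs(m) > n or (n - abs(m)) % 2 != 0:
        raise ValueError(
            f"invalid Zernike indices (n={n}, m={m}): need 0 <= |m| <= n "
            "and n - |m| even"
        )


@lru_cache(maxsize=256)
def _radial_coeffs(n: int, am: int) -> tuple[tuple[int, float], ...]:
    """Monomial expansion of the radial polynomial R_n^|m|.

    Returns ((power, coefficient), ...) with powers n, n-2, ..., |m|.
    """
    out = []
    for k in range((n - am) // 2 + 1):
        c = ((-1) ** k * math.factorial(n - k)) / (
            math.factorial(k)
            * math.factorial((n + am) // 2 - k)
            * math.factorial((n - am) // 2 - k)
        )
        out.append((n - 2 * k, float(c)))
    return tuple(out)


def _norm(n: int, m: int) -> float:
    return math.sqrt(n + 1.0) if m == 0 else math.sqrt(2.0 * (n + 1.0))


def zernike_term(n: int, m: int, rho, theta):
    """Evaluate the RMS-normalized Zernike term Z_n^m(rho, theta).

    ``rho`` is the radius normalized to the pupil (0..1), ``theta`` the
    azimuth in radians.  Normalization is sqrt(2(n+1)) for m != 0 and
    sqrt(n+1) for m == 0, so that each term has unit variance over the
    unit disk.
    """
    _check_nm(n, m)
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    am = abs(m)
    radial = np.zeros(np.broadcast(rho, theta).shape, dtype=float)
    for power, coef in _radial_coeffs(n, am):
        radial += coef * rho**power
    if m > 0:
        ang = np.cos(m * theta)
    elif m < 0:
        ang = np.sin(am * theta)
    else:
        ang = np.ones_like(radial)
    out = _norm(n, m) * radial * ang
    return out if out.shape else float(out)


def zernike_basis(max_order: int, rho, theta) -> np.ndarray:
    """Design matrix: one column per OSA-ordered term, one row per point."""
    rho = np.asarray(rho, dtype=float).ravel()
    theta = np.asarray(theta, dtype=float).ravel()
    cols = [
        zernike_term(*index_to_nm(j), rho, theta) for j in range(n_terms(max_order))
    ]
    return np.column_stack([np.broadcast_to(c, rho.shape) for c in cols])


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ElevationMap:
    """Gridded anterior corneal surface heights.

    ``z`` holds sag-convention heights in μm (posterior positive) on the
    rectangular grid ``ys`` × ``xs`` (mm); NaN marks missing samples.
    ``landmarks`` maps reference labels (corneal_vertex, geometric_center,
    pupil_center) to (x, y) positions in mm.
    """

    xs: np.ndarray
    ys: np.ndarray
    z: np.ndarray
    center: str = "corneal_vertex"
    diameter_mm: float = 8.0
    landmarks: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (self.ys.size, self.xs.size):
            raise ValueError(
                f"z shape {self.z.shape} does not match grid "
                f"({self.ys.size}, {self.xs.size})"
            )
        for name, v in (("xs", self.xs), ("ys", self.ys)):
            if v.size < 2:
                raise ValueError(f"{name} needs at least 2 samples")
            d = np.diff(v)
            if not np.all(d > 0):
                raise ValueError(f"{name} must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
                raise ValueError(f"{name} must be uniformly spaced")
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")
        self.landmarks = dict(self.landmarks)

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.xs, self.ys)


@dataclass
class ZernikeCoefficients:
    """Ordered Zernike coefficient vector tied to a pupil diameter.

    ANSI/OSA single-index ordering, unit-variance normalization, values in
    ``units`` (μm for both elevation and optical path difference vectors).
    """

    values: np.ndarray
    pupil_diameter_mm: float
    max_order: int = 7
    units: str = "um"
    residual_rms: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        expected = n_terms(self.max_order)
        if self.values.size != expected:
            raise ValueError(
                f"coefficient vector has length {self.values.size}, expected "
                f"{expected} for max_order={self.max_order}"
            )
        if self.pupil_diameter_mm <= 0:
            raise ValueError("pupil_diameter_mm must be positive")

    def get(self, n: int, m: int) -> float:
        return float(self.values[osa_index(n, m)])

    def set(self, n: int, m: int, value: float) -> None:
        self.values[osa_index(n, m)] = value

    def copy(self) -> "ZernikeCoefficients":
        return replace(self, values=self.values.copy())

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class RmsGroups:
    """Clinical RMS aberration groups in μm at a stated pupil.

    total: orders 2..N (piston and tilt excluded); hoa: orders 3..N;
    astigmatism: (2, ±2); coma_like: all odd orders (3, 5, 7);
    spherical_like: the rotationally symmetric (4, 0) and (6, 0) terms.
    """

    total: float
    hoa: float
    astigmatism: float
    coma_like: float
    spherical_like: float
    pupil_diameter_mm: float = 6.0


# ---------------------------------------------------------------------------
# fitting and reconstruction
# ---------------------------------------------------------------------------

def _aperture_samples(emap: ElevationMap, diameter_mm: float):
    x, y = emap.grid()
    r = np.hypot(x, y)
    inside = r <= diameter_mm / 2.0 + 1e-12
    valid = inside & np.isfinite(emap.z)
    n_inside = int(inside.sum())
    if n_inside == 0:
        raise FitError("no grid samples inside the requested aperture")
    missing_frac = 1.0 - valid.sum() / n_inside
    if missing_frac > 0.20:
        raise FitError(
            f"{missing_frac:.0%} of in-aperture samples are missing "
            "(more than the 20% allowed)"
        )
    return x[valid], y[valid], emap.z[valid]


def fit_elevation(
    emap: ElevationMap,
    diameter_mm: float = 8.0,
    max_order: int = 7,
) -> ZernikeCoefficients:
    """Least-squares Zernike decomposition of an elevation map.

    Missing samples inside the aperture are excluded (at most 20% may be
    missing).  The solution uses an orthogonal-decomposition solver
    (`numpy.linalg.lstsq`), never the normal equations.  The residual RMS
    over the fitted samples is reported on the returned vector.
    """
    xv, yv, zv = _aperture_samples(emap, diameter_mm)
    nt = n_terms(max_order)
    if zv.size < 3 * nt:
        raise FitError(
            f"need at least {3 * nt} in-aperture samples for "
            f"{nt} coefficients, got {zv.size}"
        )
    rho = np.hypot(xv, yv) / (diameter_mm / 2.0)
    theta = np.arctan2(yv, xv)
    basis = zernike_basis(max_order, rho, theta)
    coeffs, _, rank, _ = np.linalg.lstsq(basis, zv, rcond=None)
    if rank < nt:
        raise FitError(
            f"rank-deficient Zernike design matrix (rank {rank} < {nt}); "
            "sampling is too sparse or degenerate for the requested order"
        )
    resid = zv - basis @ coeffs
    return ZernikeCoefficients(
        coeffs,
        pupil_diameter_mm=diameter_mm,
        max_order=max_order,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def reconstruct(c: ZernikeCoefficients, x, y) -> np.ndarray:
    """Evaluate the surface described by ``c`` at (x, y) in mm.

    Points outside the pupil evaluate to NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    radius = c.pupil_diameter_mm / 2.0
    rho = np.hypot(x, y) / radius
    theta = np.arctan2(y, x)
    basis = zernike_basis(c.max_order, rho.ravel(), theta.ravel())
    out = (basis @ c.values).reshape(rho.shape)
    return np.where(rho <= 1.0 + 1e-12, out, np.nan)


# ---------------------------------------------------------------------------
# pupil rescaling
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _rescale_matrix(max_order: int, ratio: float) -> np.ndarray:
    """Exact linear map from coefficients on a pupil to a concentric
    sub-pupil of relative radius ``ratio``.

    Works per azimuthal frequency: R_n^|m|(ratio·ρ) is re-projected onto
    {R_k^|m|(ρ)} using the radial orthogonality
    ∫ R_j R_k ρ dρ = δ_jk / (2(j+1)); the integrals are polynomial and
    evaluated exactly with Gauss–Legendre quadrature.
    """
    nodes, weights = leggauss(40)
    rho = 0.5 * (nodes + 1.0)      # map [-1,1] -> [0,1]
    w = 0.5 * weights
    nt = n_terms(max_order)
    M = np.zeros((nt, nt))

    def radial(n: int, am: int, r: np.ndarray) -> np.ndarray:
        out = np.zeros_like(r)
        for power, coef in _radial_coeffs(n, am):
            out += coef * r**power
        return out

    for j_in in range(nt):
        n, m = index_to_nm(j_in)
        am = abs(m)
        rn_scaled = radial(n, am, ratio * rho)
        for k in range(am, n + 1, 2):
            proj = 2.0 * (k + 1) * np.sum(w * rn_scaled * radial(k, am, rho) * rho)
            if abs(proj) < 1e-14:
                continue
            j_out = osa_index(k, m if m == 0 else int(math.copysign(am, m)))
            M[j_out, j_in] += (_norm(n, m) / _norm(k, m)) * proj
    return M


def rescale_pupil(
    c: ZernikeCoefficients, new_diameter_mm: float
) -> ZernikeCoefficients:
    """Restrict a coefficient vector to a smaller concentric pupil.

    The returned coefficients describe the identical surface over the
    sub-aperture (equivalent to refitting the reconstruction there).
    Upscaling would extrapolate beyond the fitted data and is refused.
    """
    if new_diameter_mm <= 0:
        raise ValueError("new_diameter_mm must be positive")
    if new_diameter_mm > c.pupil_diameter_mm * (1 + 1e-9):
        raise ValueError(
            f"cannot rescale from {c.pupil_diameter_mm} mm up to "
            f"{new_diameter_mm} mm: extrapolation is not allowed"
        )
    ratio = new_diameter_mm / c.pupil_diameter_mm
    if abs(ratio - 1.0) < 1e-12:
        return replace(c.copy(), pupil_diameter_mm=new_diameter_mm)
    M = _rescale_matrix(c.max_order, round(ratio, 12))
    return ZernikeCoefficients(
        M @ c.values,
        pupil_diameter_mm=new_diameter_mm,
        max_order=c.max_order,
        units=c.units,
    )


# ---------------------------------------------------------------------------
# wavefront conversion and RMS groups
# ---------------------------------------------------------------------------

def elevation_to_wavefront(
    c: ZernikeCoefficients, delta_n: float = DEFAULT_DELTA_N
) -> ZernikeCoefficients:
    """First-surface elevation → optical path difference (both μm).

    Each coefficient is multiplied by the refractive index step ``delta_n``
    (air → corneal stroma, default 0.376); the operator is linear.
    """
    out = c.copy()
    out.values = out.values * float(delta_n)
    out.residual_rms = None
    return out


def rms_groups(
    c: ZernikeCoefficients, pupil_diameter_mm: float = 6.0
) -> RmsGroups:
    """Clinical RMS aberration groups at the requested pupil.

    The vector is rescaled down to ``pupil_diameter_mm`` when needed;
    asking for a larger pupil than the fit supports is an error.  Under
    unit-variance normalization each group RMS is the Euclidean norm of
    its coefficients; piston and tilt are excluded everywhere.
    """
    if pupil_diameter_mm > c.pupil_diameter_mm * (1 + 1e-9):
        raise ValueError(
            f"RMS groups requested at {pupil_diameter_mm} mm but coefficients "
            f"are only valid to {c.pupil_diameter_mm} mm"
        )
    if pupil_diameter_mm < c.pupil_diameter_mm * (1 - 1e-9):
        c = rescale_pupil(c, pupil_diameter_mm)
    v = c.values
    nm = [index_to_nm(j) for j in range(v.size)]

    def rms_of(sel) -> float:
        idx = [j for j, (n, m) in enumerate(nm) if sel(n, m)]
        return float(np.sqrt(np.sum(v[idx] ** 2))) if idx else 0.0

    return RmsGroups(
        total=rms_of(lambda n, m: n >= 2),
        hoa=rms_of(lambda n, m: n >= 3),
        astigmatism=rms_of(lambda n, m: n == 2 and abs(m) == 2),
        coma_like=rms_of(lambda n, m: n >= 3 and n % 2 == 1),
        spherical_like=rms_of(lambda n, m: m == 0 and n in (4, 6)),
        pupil_diameter_mm=pupil_diameter_mm,
    )
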