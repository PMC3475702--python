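"""Axisymmetric contours in the arc-length / tangent-angle parametrization.

An axisymmetric membrane shape is described by the tangent angle psi(s)
along a longitude, with arc length s running from the pole (s = 0, where
the radial coordinate r vanishes) to the rim (s = s1, where the bud joins
the surrounding flat membrane).  The generating curve obeys

    dr/ds = cos(psi),    dz/ds = sin(psi),

and the principal curvatures are c1 = dpsi/ds (along the longitude) and
c2 = sin(psi)/r (along the circle of latitude).  At the pole the second
curvature is regularized by its limit c2 -> c1.

The bud shape itself is held as a truncated sine series

    psi(s) = sum_n a_n sin(n * pi * s / s1),

which enforces psi(0) = psi(s1) = 0 so that the contour starts at a
regular pole and connects smoothly to a flat reservoir membrane at the rim.
The ESCRT-rich ring Gamma occupies arc lengths [s_a, s_b].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_simpson, simpson
from scipy.interpolate import CubicSpline


class InvalidShapeError(ValueError):
    """Signals a geometrically inadmissible contour (r < 0 somewhere)."""


#: relative tolerance below which r is treated as zero (pole / closed neck)
_R_POLE_RTOL = 1e-9


@dataclass(frozen=True)
class ShapeProfile:
    """Fourier-sine representation of the tangent angle of a bud contour.

    Attributes
    ----------
    amplitudes : ndarray
        Ordered amplitudes a_1..a_N of sin(n pi s / s1).
    s1 : float
        Total contour length from pole to rim.
    s_a, s_b : float
        Arc-length positions of the inner and outer boundary of the
        ESCRT-rich ring, 0 <= s_a <= s_b <= s1.
    """

    amplitudes: np.ndarray
    s1: float
    s_a: float
    s_b: float

    def __post_init__(self) -> None:
        amps = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        object.__setattr__(self, "amplitudes", amps)
        if amps.ndim != 1 or amps.size < 1:
            raise ValueError("amplitudes must be a 1-d array with N >= 1")
        if not (self.s1 > 0):
            raise ValueError(f"s1 must be positive, got {self.s1}")
        if not (0.0 <= self.s_a <= self.s_b <= self.s1 * (1 + 1e-12)):
            raise ValueError(
                f"ring boundaries must satisfy 0 <= s_a <= s_b <= s1, got "
                f"s_a={self.s_a}, s_b={self.s_b}, s1={self.s1}"
            )

    @property
    def n_modes(self) -> int:
        return int(self.amplitudes.size)

    def with_s1(self, s1: float) -> "ShapeProfile":
        """Rescale the contour length, carrying the ring boundaries along.

        The amplitudes are dimensionless (they multiply sin(n pi s/s1)), so
        changing s1 rescales the whole shape uniformly; the ring boundaries
        are kept at fixed fractions of s1.
        """
        ratio = s1 / self.s1
        return replace(self, s1=s1, s_a=self.s_a * ratio, s_b=self.s_b * ratio)


def eval_psi(profile: ShapeProfile, s) -> np.ndarray | float:
    """Evaluate the tangent angle psi(s) of the sine series.

    ``s`` may be a scalar or array; every value must lie in [0, s1].
    psi(0) = psi(s1) = 0 hold exactly by construction of the basis.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < -1e-12) or np.any(s_arr > profile.s1 * (1 + 1e-12)):
        raise ValueError(f"arc length outside [0, s1={profile.s1}]")
    n = np.arange(1, profile.n_modes + 1)
    phase = np.multiply.outer(s_arr / profile.s1, n * np.pi)
    psi = np.sin(phase) @ profile.amplitudes
    return psi if np.ndim(s) else float(psi)


def eval_dpsi_ds(profile: ShapeProfile, s) -> np.ndarray | float:
    """Evaluate dpsi/ds of the sine series (the meridional curvature c1)."""
    s_arr = np.asarray(s, dtype=float)
    n = np.arange(1, profile.n_modes + 1)
    k = n * np.pi / profile.s1
    phase = np.multiply.outer(s_arr / profile.s1, n * np.pi)
    dpsi = np.cos(phase) @ (profile.amplitudes * k)
    return dpsi if np.ndim(s) else float(dpsi)


@dataclass(frozen=True)
class Contour:
    """A sampled axisymmetric contour with curvatures and quadrature weights.

    The arrays are sampled on a uniform grid in s (odd node count) so that
    composite Simpson weights integrate smooth integrands to high order.
    ``s_a``/``s_b`` record the ESCRT ring if the contour was built from a
    profile or fixture that carries one.
    """

    s: np.ndarray
    r: np.ndarray
    z: np.ndarray
    psi: np.ndarray
    c1: np.ndarray
    c2: np.ndarray
    weights: np.ndarray
    s_a: float | None = None
    s_b: float | None = None
    _r_spline: CubicSpline = field(repr=False, compare=False, default=None)

    @property
    def s1(self) -> float:
        return float(self.s[-1])

    def r_at(self, s: float | np.ndarray):
        """Interpolated radial coordinate r(s)."""
        return self._spline()(s)

    def _spline(self) -> CubicSpline:
        if self._r_spline is None:
            object.__setattr__(self, "_r_spline", CubicSpline(self.s, self.r))
        return self._r_spline

    def integrate(self, values: np.ndarray) -> float:
        """Integrate node values over the full contour with the weights."""
        return float(self.weights @ values)

    def rescaled(self, factor: float) -> "Contour":
        """Uniformly rescale all lengths by ``factor`` (curvatures by 1/factor)."""
        return Contour(
            s=self.s * factor,
            r=self.r * factor,
            z=self.z * factor,
            psi=self.psi.copy(),
            c1=self.c1 / factor,
            c2=self.c2 / factor,
            weights=self.weights * factor,
            s_a=None if self.s_a is None else self.s_a * factor,
            s_b=None if self.s_b is None else self.s_b * factor,
        )


def _simpson_weights(n_nodes: int, h: float) -> np.ndarray:
    if n_nodes < 3 or n_nodes % 2 == 0:
        raise ValueError("composite Simpson needs an odd node count >= 3")
    w = np.ones(n_nodes)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * (h / 3.0)


def _regularized_c2(psi, r, c1) -> np.ndarray:
    """sin(psi)/r with the pole limit c2 -> c1 where r vanishes."""
    r_ref = max(float(np.max(np.abs(r))), 1e-300)
    near_zero = np.abs(r) <= _R_POLE_RTOL * r_ref
    safe_r = np.where(near_zero, 1.0, r)
    return np.where(near_zero, c1, np.sin(psi) / safe_r)


def reconstruct_contour(profile: ShapeProfile, n_nodes: int = 1025) -> Contour:
    """Quadrature reconstruction of (r, z) and curvatures from a profile.

    r and z are obtained by cumulative Simpson integration of cos(psi) and
    sin(psi) on a uniform grid; raises :class:`InvalidShapeError` if the
    reconstructed r dips below zero anywhere (used by the minimizer to
    reject inadmissible moves).
    """
    if n_nodes % 2 == 0:
        n_nodes += 1
    s = np.linspace(0.0, profile.s1, n_nodes)
    psi = eval_psi(profile, s)
    c1 = eval_dpsi_ds(profile, s)
    r = cumulative_simpson(np.cos(psi), x=s, initial=0.0)
    z = cumulative_simpson(np.sin(psi), x=s, initial=0.0)
    if np.min(r) < -1e-9 * profile.s1:
        raise InvalidShapeError(
            f"negative radial coordinate (min r = {np.min(r):.3e})"
        )
    r = np.maximum(r, 0.0)
    c2 = _regularized_c2(psi, r, c1)
    h = s[1] - s[0]
    return Contour(
        s=s, r=r, z=z, psi=psi, c1=c1, c2=c2,
        weights=_simpson_weights(n_nodes, h),
        s_a=profile.s_a, s_b=profile.s_b,
    )


def contour_from_closed_form(
    s1: float,
    psi_fn,
    c1_fn,
    r_fn=None,
    n_nodes: int = 1025,
    s_a: float | None = None,
    s_b: float | None = None,
) -> Contour:
    """Build a contour by sampling closed-form psi(s) (and optionally r(s)).

    Used by the fixture generator: when the exact r(s) is known it is
    sampled directly rather than integrated, so pointwise identities such
    as c1 + c2 = 0 on a catenoid hold to machine precision.
    """
    if n_nodes % 2 == 0:
        n_nodes += 1
    s = np.linspace(0.0, s1, n_nodes)
    psi = np.asarray(psi_fn(s), dtype=float)
    c1 = np.asarray(c1_fn(s), dtype=float)
    if r_fn is not None:
        r = np.asarray(r_fn(s), dtype=float)
    else:
        r = cumulative_simpson(np.cos(psi), x=s, initial=0.0)
    if np.min(r) < -1e-9 * s1:
        raise InvalidShapeError("negative radial coordinate in closed form")
    r = np.maximum(r, 0.0)
    z = cumulative_simpson(np.sin(psi), x=s, initial=0.0)
    c2 = _regularized_c2(psi, r, c1)
    h = s[1] - s[0]
    return Contour(
        s=s, r=r, z=z, psi=psi, c1=c1, c2=c2,
        weights=_simpson_weights(n_nodes, h), s_a=s_a, s_b=s_b,
    )


def surface_area(contour: Contour, s_lo: float = 0.0, s_hi: float | None = None) -> float:
    """Membrane area 2*pi * integral of r ds over [s_lo, s_hi]."""
    if s_hi is None:
        s_hi = contour.s1
    if s_lo > s_hi:
        raise ValueError(f"inverted range [{s_lo}, {s_hi}]")
    if s_lo < -1e-12 or s_hi > contour.s1 * (1 + 1e-12):
        raise ValueError("range outside contour domain")
    spline = contour._spline()
    return 2.0 * np.pi * float(spline.integrate(s_lo, min(s_hi, contour.s1)))


def boundary_radius(contour: Contour, s: float) -> float:
    """Radial distance r(s) from the symmetry axis, by interpolation."""
    return float(contour.r_at(np.clip(s, 0.0, contour.s1)))


def contour_to_frame(contour: Contour):
    """Contour as a pandas DataFrame with the standard export columns."""
    import pandas as pd

    in_ring = np.zeros(contour.s.size, dtype=int)
    if contour.s_a is not None and contour.s_b is not None:
        in_ring[(contour.s >= contour.s_a) & (contour.s <= contour.s_b)] = 1
    return pd.DataFrame(
        {
            "s": contour.s,
            "r": contour.r,
            "z": contour.z,
            "psi": contour.psi,
            "c1": contour.c1,
            "c2": contour.c2,
            "in_escrt_ring": in_ring,
        }
    )
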