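"""Closed-form reference shapes: flat disc, spherical cap, sphere-with-neck.

Every fixture is generated programmatically from its closed form; the
``reference`` dictionary carries the exact quantities (areas, bending
energies, radii) the closed form implies, so tests can compare quadrature
against analytic truth without stored data.

The fitted :class:`~budkit.geometry.ShapeProfile` attached to a fixture is
a least-squares sine-series approximation of the closed-form tangent
angle.  The fit interval is the physically meaningful part of the contour;
beyond it the series is free (lightly ridge-regularized), which is what
lets a truncated sine basis -- whose every term vanishes at s1 -- track a
tangent angle that is nonzero at the end of the fit interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Contour, ShapeProfile, contour_from_closed_form, _regularized_c2, _simpson_weights


@dataclass(frozen=True)
class Fixture:
    """A reference shape: exact contour, fitted profile, exact quantities."""

    name: str
    contour: Contour
    profile: ShapeProfile | None
    fit_max_error: float
    reference: dict


def fit_profile_to_psi(
    psi_fn,
    s_fit_end: float,
    s1: float,
    n_modes: int = 30,
    n_sample: int = 801,
    ridge: float = 1e-8,
    s_a: float = 0.0,
    s_b: float | None = None,
) -> tuple[ShapeProfile, float]:
    """Least-squares fit of a sine series to a target tangent angle.

    Fits psi(s) = sum a_n sin(n pi s / s1) to ``psi_fn`` on [0, s_fit_end]
    with s_fit_end <= s1; a small ridge penalty on n^2 * a_n keeps the
    unconstrained tail of the series smooth.  Returns the profile and the
    max absolute fit error on the fit interval.
    """
    if not (0 < s_fit_end <= s1):
        raise ValueError("need 0 < s_fit_end <= s1")
    s = np.linspace(0.0, s_fit_end, n_sample)
    target = np.asarray(psi_fn(s), dtype=float)
    n = np.arange(1, n_modes + 1)
    basis = np.sin(np.outer(s / s1, n * np.pi))
    reg = ridge * np.diag(n.astype(float) ** 2)
    lhs = basis.T @ basis + reg.T @ reg
    amps = np.linalg.solve(lhs, basis.T @ target)
    err = float(np.max(np.abs(basis @ amps - target)))
    return ShapeProfile(amplitudes=amps, s1=s1, s_a=s_a,
                        s_b=s1 if s_b is None else s_b), err


def make_flat(radius: float = 1.0, n_modes: int = 30, n_nodes: int = 1025) -> Fixture:
    """Flat disc of the given radius; the trivial zero-bending reference."""
    contour = contour_from_closed_form(
        radius, lambda s: 0.0 * s, lambda s: 0.0 * s,
        r_fn=lambda s: np.asarray(s, float),
        n_nodes=n_nodes, s_a=0.0, s_b=radius,
    )
    profile = ShapeProfile(np.zeros(n_modes), radius, 0.0, radius)
    return Fixture(
        name="flat",
        contour=contour,
        profile=profile,
        fit_max_error=0.0,
        reference={
            "area": np.pi * radius**2,
            "e_bend_kappa": 0.0,
            "rim_radius": radius,
            "line_length": 2 * np.pi * radius,
        },
    )


def make_cap(x: float, domain_area: float = np.pi,
             n_modes: int = 30, n_nodes: int = 1025) -> Fixture:
    """Spherical cap at budding coordinate x, whole domain on the cap.

    x = 0.5 is a hemisphere (bending energy 4*pi*kappa), x = 1 the closed
    sphere (8*pi*kappa); the cap base radius is a*sqrt(1-x) with
    a = sqrt(domain_area/pi).
    """
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"budding coordinate x must be in [0,1], got {x}")
    from .cap import cap_contour

    a_scale = float(np.sqrt(domain_area / np.pi))
    cc = cap_contour(x, 1.0, "I", n_nodes)
    contour = cc.contour.rescaled(a_scale)
    profile, err = (None, np.nan)
    if x > 1e-12:
        rho = a_scale * 0.5 / np.sqrt(x)
        alpha = float(np.arccos(1.0 - 2.0 * x))
        s_cap = rho * alpha
        profile, err = fit_profile_to_psi(
            lambda s: s / rho, s_cap, s_cap / 0.7, n_modes)
    return Fixture(
        name=f"cap_x{x:g}",
        contour=contour,
        profile=profile,
        fit_max_error=err,
        reference={
            "area": domain_area,
            "e_bend_kappa": 8.0 * np.pi * x,
            "base_radius": a_scale * np.sqrt(1.0 - x),
            "cap_radius": a_scale * 0.5 / np.sqrt(max(x, 1e-300)),
        },
    )


def make_sphere_with_catenoid_neck(
    bud_radius: float = 1.0,
    neck_radius: float = 0.15,
    psi_end: float = 0.15,
    n_nodes: int = 2049,
    n_modes: int = 30,
) -> Fixture:
    """Spherical bud joined to a catenoidal neck, the coatless-bud geometry.

    The sphere (radius R) is matched to a catenoid (waist radius c) with
    continuous tangent angle and radius at the junction; the catenoid is
    the zero-mean-curvature neck, truncated where the tangent angle falls
    to ``psi_end``.  As c -> 0 the bending energy approaches that of a
    closed sphere, 8*pi*kappa.
    """
    R, c = float(bud_radius), float(neck_radius)
    if not (0 < c < R):
        raise ValueError("need 0 < neck_radius < bud_radius")
    if not (0 < psi_end < np.pi / 4):
        raise ValueError("psi_end must be in (0, pi/4)")
    # junction: catenoid arc parameter sig_j < 0 (sphere side of the waist)
    sig_j = -np.sqrt(R * c - c * c)
    theta_j = float(np.arccos(sig_j / np.sqrt(R * c)))  # > pi/2
    s_j = R * theta_j
    sig_end = c / np.tan(psi_end)
    s1 = s_j + (sig_end - sig_j)

    half = (n_nodes // 2) | 1
    s_sph = np.linspace(0.0, s_j, half)
    psi_sph = s_sph / R
    r_sph = R * np.sin(psi_sph)
    z_sph = R * (1.0 - np.cos(psi_sph))
    c1_sph = np.full(half, 1.0 / R)
    w_sph = _simpson_weights(half, s_sph[1] - s_sph[0])

    sig = np.linspace(sig_j, sig_end, half)
    s_cat = s_j + (sig - sig_j)
    hyp = np.sqrt(sig**2 + c**2)
    psi_cat = np.arccos(sig / hyp)
    r_cat = hyp
    c1_cat = -c / (sig**2 + c**2)
    z_cat = z_sph[-1] + (c * np.arcsinh(sig / c) - c * np.arcsinh(sig_j / c))
    w_cat = _simpson_weights(half, s_cat[1] - s_cat[0])

    # share the junction node: panel weights add, c1 takes the mean of the
    # one-sided limits (psi and r are continuous there)
    s_all = np.concatenate([s_sph, s_cat[1:]])
    r_all = np.concatenate([r_sph, r_cat[1:]])
    z_all = np.concatenate([z_sph, z_cat[1:]])
    psi_all = np.concatenate([psi_sph, psi_cat[1:]])
    c1_all = np.concatenate([c1_sph, c1_cat[1:]])
    c1_all[half - 1] = 0.5 * (c1_sph[-1] + c1_cat[0])
    w_all = np.concatenate([w_sph, w_cat[1:]])
    w_all[half - 1] = w_sph[-1] + w_cat[0]
    c2_all = _regularized_c2(psi_all, r_all, c1_all)

    # ring over the pure-catenoid nodes (junction node excluded: its c1 is
    # the average of two one-sided limits, not a curvature of either piece)
    s_a_ring = float(s_cat[1])
    contour = Contour(
        s=s_all, r=r_all, z=z_all, psi=psi_all, c1=c1_all, c2=c2_all,
        weights=w_all, s_a=s_a_ring, s_b=s1,
    )

    def psi_fn(s):
        s = np.asarray(s, float)
        sig_of_s = sig_j + (s - s_j)
        return np.where(
            s <= s_j, s / R,
            np.arccos(sig_of_s / np.sqrt(sig_of_s**2 + c**2)),
        )

    profile, err = fit_profile_to_psi(psi_fn, s1, s1 / 0.85, n_modes,
                                      s_a=s_a_ring, s_b=s1)
    e_bend_exact = 4.0 * np.pi * (1.0 + np.sqrt(1.0 - c / R))
    return Fixture(
        name=f"sphere_neck_R{R:g}_c{c:g}",
        contour=contour,
        profile=profile,
        fit_max_error=err,
        reference={
            "e_bend_kappa": e_bend_exact,
            "neck_radius": c,
            "bud_radius": R,
            "junction_s": s_j,
            "junction_psi": theta_j,
        },
    )
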