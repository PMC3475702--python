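"""Analytic spherical-cap model: energies, phase diagram, budding pathways.

This is the single transcription point for the closed-form cap energies;
every other module calls these functions rather than re-deriving them.

Geometry
--------
The nascent bud is approximated by a spherical cap of radius ``rho`` and
budding angle ``alpha``; the budding coordinate is x = (1 - cos alpha)/2,
so x = 0 is flat and x = 1 a complete spherical bud.  The area ratio
phi = A_Gamma / A_Omega in [0, 1] locates the ESCRT-rich ring Gamma within
the lipid domain Omega.  In units of kappa, with p_sigma = sigma*a/kappa
(a = sqrt(A/pi)), p_w = w*A/kappa and p_g = delta_kappa_g/kappa:

The Gaussian-coupling term of a ring collapses by Gauss-Bonnet to
2*pi*dkg*(cos psi_in - cos psi_out) with the tangent angles at the ring
boundaries; the ring's outer boundary coincides with the domain rim, i.e.
it includes the matching kink to the surrounding flat membrane, so
psi_out = 0.  (This is also what the smooth full model does: a ring
reaching the rim spans the neck, and only the boundary angles matter.)

Case I  (the whole lipid domain forms the cap, Gamma a ring reaching the rim)::

    E_I(x, phi)  = 8*pi*x - 4*pi*p_g*x*(1 - phi) + 2*pi*p_sigma*sqrt(1 - x) - p_w*phi

  Derivation: cap area A fixes rho^2 = A/(4*pi*x); bending (kappa/2)(2/rho)^2 A
  = 8*pi*kappa*x; the rim radius is a*sqrt(1-x); the ring of area phi*A has
  inner boundary angle theta_a with cos(theta_a) = 1 - 2*x*(1-phi), so the
  Gaussian coupling is 2*pi*dkg*(cos theta_a - 1) = -4*pi*dkg*x*(1-phi).

Case II (only the ESCRT-free patch of area (1-phi)A buds; Gamma stays as a
flat annulus wrapped around the bud neck)::

    E_II(x, phi) = 8*pi*x - 4*pi*p_g*x + 2*pi*p_sigma*sqrt(1 - x*(1-phi)) - p_w*phi

  The Gaussian coupling now comes entirely from the neck kink where the
  tangent angle drops from alpha to 0 across Gamma's inner boundary:
  2*pi*dkg*(cos alpha - 1) = -4*pi*dkg*x.

The two cases coincide along phi = 0 (a bare cap with the ESCRTs pinched
at the neck) and reduce to the flat-domain energy 2*pi*p_sigma - p_w*phi
at x = 0.  For non-degenerate parameters the determinant of the 2x2
Hessian of either case is negative throughout the open unit square
(E_I: -(4*pi*p_g)^2; E_II: strictly negative for p_sigma > 0), so minima
sit on the corners:

    flat               (0, 1):  2*pi*p_sigma - p_w
    coated bud         (1, 1)I: 8*pi - p_w
    coatless-bud limit (1, 1)II: 8*pi - 4*pi*p_g + 2*pi*p_sigma - p_w
                                 (zero-radius ESCRT-free "mini-bud")
    neck-ESCRT bud     (1, 0):  8*pi - 4*pi*p_g
                                 (sphere of radius sqrt(A/4pi), ESCRTs in neck)

Pathways follow the unit-square edges: (0,1) -> (1,1) along phi = 1, then
(1,1) -> (1,0) along x = 1, on surface I when p_g < 2 (three-stage route)
and on surface II when p_g > 2 (mini-bud route).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .energy import EnergyBreakdown
from .geometry import Contour, contour_from_closed_form
from .params import DimensionlessParams, MembraneParams, nondimensionalize


def _as_dimensionless(params) -> DimensionlessParams:
    if isinstance(params, MembraneParams):
        return nondimensionalize(params)
    if isinstance(params, DimensionlessParams):
        return params
    raise TypeError(f"unsupported parameter type {type(params)!r}")


@dataclass(frozen=True)
class CapState:
    """A point of the cap model: coordinates, case, and energy in kappa units."""

    x: float
    phi: float
    case_label: str
    energy: float


def _check_square(x: float, phi: float) -> None:
    if not (0.0 <= x <= 1.0 and 0.0 <= phi <= 1.0):
        raise ValueError(f"(x, phi) = ({x}, {phi}) outside the unit square")


def cap_energy(x: float, phi: float, params, case_label: str = "I") -> float:
    """Closed-form cap energy of the chosen case, in units of kappa."""
    _check_square(x, phi)
    dp = _as_dimensionless(params)
    if case_label == "I":
        return float(
            8.0 * np.pi * x
            - 4.0 * np.pi * dp.p_g * x * (1.0 - phi)
            + 2.0 * np.pi * dp.p_sigma * np.sqrt(1.0 - x)
            - dp.p_w * phi
        )
    if case_label == "II":
        return float(
            (8.0 * np.pi - 4.0 * np.pi * dp.p_g) * x
            + 2.0 * np.pi * dp.p_sigma * np.sqrt(1.0 - x * (1.0 - phi))
            - dp.p_w * phi
        )
    raise ValueError(f"case_label must be 'I' or 'II', got {case_label!r}")


# ---------------------------------------------------------------------------
# quadrature cross-validation: evaluate the full functional on cap contours
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CapContour:
    """Exact cap-model contour plus ring metadata for the quadrature oracle.

    ``psi_a``/``psi_b`` are the tangent angles at the ring boundaries, with
    ``psi_a`` taken on the cap side of the Case-II neck kink so that the
    Gaussian boundary form sees the kink.  ``ring_area`` is the ring area
    obtained by quadrature on the contour panels.
    """

    contour: Contour
    s_a: float
    s_b: float
    psi_a: float
    psi_b: float
    ring_area: float


def _flat_cap_contour(phi: float, s_a: float, s_b: float, n_nodes: int) -> CapContour:
    cont = contour_from_closed_form(
        1.0, lambda s: 0.0 * s, lambda s: 0.0 * s, r_fn=lambda s: np.asarray(s, float),
        n_nodes=n_nodes, s_a=s_a, s_b=s_b,
    )
    return CapContour(cont, s_a, s_b, 0.0, 0.0,
                      float(np.pi * (s_b**2 - s_a**2)))


def cap_contour(
    x: float, phi: float, case_label: str = "I", n_nodes: int = 1025
) -> CapContour:
    """Exact cap contour (dimensionless, lengths in units of a = sqrt(A/pi)).

    Case I samples the spherical cap in closed form; Case II is piecewise
    (cap + flat annulus) with the junction as a quadrature panel boundary.
    """
    _check_square(x, phi)
    from .geometry import _regularized_c2, _simpson_weights

    if x < 1e-12:
        # flat disc of radius 1, ring of area phi*pi at the rim
        return _flat_cap_contour(phi, float(np.sqrt(1.0 - phi)), 1.0, n_nodes)

    alpha = float(np.arccos(1.0 - 2.0 * x))
    if case_label == "I":
        rho = 0.5 / np.sqrt(x)                     # rho^2 = 1/(4x), A = pi
        s1 = rho * alpha
        cos_theta_a = (1.0 - 2.0 * x) + 2.0 * phi * x
        theta_a = float(np.arccos(np.clip(cos_theta_a, -1.0, 1.0)))
        s_a, s_b = rho * theta_a, s1
        cont = contour_from_closed_form(
            s1,
            lambda s: s / rho,
            lambda s: np.full_like(np.asarray(s, float), 1.0 / rho),
            r_fn=lambda s: rho * np.sin(s / rho),
            n_nodes=n_nodes, s_a=s_a, s_b=s_b,
        )
        from .geometry import surface_area

        # psi_b = 0: the ring's outer boundary is the rim including the
        # matching kink (tangent angle alpha -> 0) to the flat reservoir
        return CapContour(cont, s_a, s_b, theta_a, 0.0,
                          surface_area(cont, s_a, s_b))

    if case_label != "II":
        raise ValueError(f"case_label must be 'I' or 'II', got {case_label!r}")

    # Case II: cap of area (1-phi)*pi plus flat annulus Gamma of area phi*pi.
    # phi -> 1 is the zero-radius mini-bud: by scale invariance its bending
    # and kink terms survive, so represent it by a tiny (not absent) cap.
    phi = min(phi, 1.0 - 1e-9)
    rho = 0.5 * np.sqrt((1.0 - phi) / x)
    s_cap = rho * alpha
    r_base = float(np.sqrt((1.0 - phi) * (1.0 - x)))
    r_out = float(np.sqrt(1.0 - x * (1.0 - phi)))
    ds_annulus = r_out - r_base
    s1 = s_cap + ds_annulus

    half = (n_nodes // 2) | 1  # odd node count per panel
    s_c = np.linspace(0.0, s_cap, half)
    psi_c = s_c / rho
    r_c = rho * np.sin(psi_c)
    c1_c = np.full(half, 1.0 / rho)
    z_c = rho * (1.0 - np.cos(psi_c))
    w_c = _simpson_weights(half, s_c[1] - s_c[0])
    if ds_annulus > 1e-12:
        s_f = np.linspace(s_cap, s1, half)
        r_f = r_base + (s_f - s_cap)
        w_f = _simpson_weights(half, s_f[1] - s_f[0])
        ring_area = float(2.0 * np.pi * (w_f @ r_f))
        s_all = np.concatenate([s_c, s_f])
        r_all = np.concatenate([r_c, r_f])
        psi_all = np.concatenate([psi_c, np.zeros(half)])
        c1_all = np.concatenate([c1_c, np.zeros(half)])
        z_all = np.concatenate([z_c, np.full(half, z_c[-1])])
        w_all = np.concatenate([w_c, w_f])
    else:
        s_all, r_all, psi_all, c1_all, z_all, w_all = (
            s_c, r_c, psi_c, c1_c, z_c, w_c)
        ring_area = 0.0

    c2_all = _regularized_c2(psi_all, r_all, c1_all)
    cont = Contour(
        s=s_all, r=r_all, z=z_all, psi=psi_all, c1=c1_all, c2=c2_all,
        weights=w_all, s_a=s_cap, s_b=s1,
    )
    return CapContour(cont, s_cap, s1, alpha, 0.0, ring_area)


def cap_energy_by_quadrature(
    x: float, phi: float, params, case_label: str = "I", n_nodes: int = 2049
) -> EnergyBreakdown:
    """Evaluate the full arc-length functional on the exact cap contour.

    Independent cross-check of :func:`cap_energy`: bending, line and
    binding terms by quadrature on the contour; Gaussian coupling by the
    boundary form with the ring-boundary angles (including the Case-II
    neck kink).  Dimensionless output in units of kappa.
    """
    dp = _as_dimensionless(params)
    cc = cap_contour(x, phi, case_label, n_nodes)
    from .energy import bending_energy, line_energy

    return EnergyBreakdown(
        e_bend=bending_energy(cc.contour, dp),
        e_gauss=float(2.0 * np.pi * dp.p_g
                      * (np.cos(cc.psi_a) - np.cos(cc.psi_b))),
        e_line=line_energy(cc.contour, dp),
        e_bind=float(-(dp.p_w / np.pi) * cc.ring_area),
    )


# ---------------------------------------------------------------------------
# corners, Hessian, global minimum
# ---------------------------------------------------------------------------

CORNER_FLAT = "flat"
CORNER_COATED = "coated_bud"
CORNER_MINI = "coatless_bud_limit"
CORNER_NECK = "neck_escrt_bud"

#: morphology label of each corner state
CORNER_MORPHOLOGY = {
    CORNER_FLAT: "flat",
    CORNER_COATED: "coated_bud",
    CORNER_MINI: "coatless_bud",
    CORNER_NECK: "coatless_bud",
}


def corner_energies(params) -> dict[str, CapState]:
    """The four labeled corner states of the unit square.

    ``flat`` is (0,1); ``coated_bud`` is (1,1) on surface I; the
    ``coatless_bud_limit`` is (1,1) on surface II (the zero-radius
    ESCRT-free mini-bud); ``neck_escrt_bud`` is (1,0) on surface II, the
    complete coatless bud of radius sqrt(A/4pi) with ESCRTs in the neck.
    """
    dp = _as_dimensionless(params)
    return {
        CORNER_FLAT: CapState(0.0, 1.0, "I", cap_energy(0.0, 1.0, dp, "I")),
        CORNER_COATED: CapState(1.0, 1.0, "I", cap_energy(1.0, 1.0, dp, "I")),
        CORNER_MINI: CapState(1.0, 1.0, "II", cap_energy(1.0, 1.0, dp, "II")),
        CORNER_NECK: CapState(1.0, 0.0, "II", cap_energy(1.0, 0.0, dp, "II")),
    }


def hessian_sign_scan(
    params, grid_n: int = 21, case_label: str = "I", step: float = 1e-5
) -> np.ndarray:
    """Sign of det(Hessian) of the case energy on an interior grid.

    Central finite differences; returns the (grid_n x grid_n) array of
    signs (-1, 0, +1).  For non-degenerate parameters the determinant is
    negative everywhere in the open square, which confines minima to the
    boundary.  Degenerate limits (p_g = 0 for Case I, p_sigma = 0 for
    Case II) have singular Hessians and are excluded from that claim.
    """
    dp = _as_dimensionless(params)
    xs = np.linspace(step * 4, 1.0 - step * 4, grid_n + 2)[1:-1]
    phis = np.linspace(step * 4, 1.0 - step * 4, grid_n + 2)[1:-1]
    signs = np.zeros((grid_n, grid_n))
    e = lambda x, p: cap_energy(x, p, dp, case_label)
    for i, x in enumerate(xs):
        for j, p in enumerate(phis):
            exx = (e(x + step, p) - 2 * e(x, p) + e(x - step, p)) / step**2
            epp = (e(x, p + step) - 2 * e(x, p) + e(x, p - step)) / step**2
            exp_ = (
                e(x + step, p + step) - e(x + step, p - step)
                - e(x - step, p + step) + e(x - step, p - step)
            ) / (4 * step**2)
            signs[i, j] = np.sign(exx * epp - exp_**2)
    return signs


def global_minimum(params, check_grid_n: int = 41) -> CapState:
    """Lowest-energy corner state, with an interior consistency check.

    The Hessian property confines local minima to the unit-square
    boundary; a dense-grid scan over both case surfaces verifies that no
    interior or edge point undercuts the best corner (saddles that emerge
    inside the square lie above the corner minima).
    """
    dp = _as_dimensionless(params)
    corners = corner_energies(dp)
    best_name = min(corners, key=lambda k: corners[k].energy)
    best = corners[best_name]
    xs = np.linspace(0.0, 1.0, check_grid_n)
    ps = np.linspace(0.0, 1.0, check_grid_n)
    xg, pg_ = np.meshgrid(xs, ps, indexing="ij")
    e1 = (8 * np.pi * xg - 4 * np.pi * dp.p_g * xg * (1 - pg_)
          + 2 * np.pi * dp.p_sigma * np.sqrt(1 - xg) - dp.p_w * pg_)
    e2 = ((8 * np.pi - 4 * np.pi * dp.p_g) * xg
          + 2 * np.pi * dp.p_sigma * np.sqrt(1 - xg * (1 - pg_)) - dp.p_w * pg_)
    grid_min = float(min(e1.min(), e2.min()))
    if grid_min < best.energy - 1e-6 * (1.0 + abs(best.energy)):
        raise RuntimeError(
            f"interior grid point ({grid_min:.6g}) undercuts corner minimum "
            f"({best.energy:.6g}); corner-minimum property violated"
        )
    return best


def minimum_morphology(params) -> str:
    """Morphology label (flat | coated_bud | coatless_bud) of the global minimum."""
    dp = _as_dimensionless(params)
    corners = corner_energies(dp)
    return CORNER_MORPHOLOGY[min(corners, key=lambda k: corners[k].energy)]


# ---------------------------------------------------------------------------
# edge-path barriers and the phase diagram
# ---------------------------------------------------------------------------

def edge_path_energy(params, case_label: str, n_per_leg: int = 801):
    """Energy along the budding edge path (0,1)->(1,1) in x, then (1,1)->(1,0) in phi."""
    dp = _as_dimensionless(params)
    x_leg = np.linspace(0.0, 1.0, n_per_leg)
    phi_leg = np.linspace(1.0, 0.0, n_per_leg)
    e1 = np.array([cap_energy(x, 1.0, dp, case_label) for x in x_leg])
    e2 = np.array([cap_energy(1.0, p, dp, case_label) for p in phi_leg])
    t = np.concatenate([x_leg, 1.0 + (1.0 - phi_leg)])
    return t, np.concatenate([e1, e2])


def edge_path_barrier(params, case_label: str = "I", n_per_leg: int = 2001) -> float:
    """Barrier along the edge path: max(E along path) - E(start), >= 0."""
    _, e = edge_path_energy(params, case_label, n_per_leg)
    return float(max(np.max(e) - e[0], 0.0))


@dataclass(frozen=True)
class PhaseDiagram:
    """Morphology labels and transition curves over a (p_sigma, p_w) grid."""

    p_sigma: np.ndarray
    p_w: np.ndarray
    p_g: float
    labels: np.ndarray            # (n_sigma, n_w) array of label strings
    e_min: np.ndarray             # corner-minimum energy at each grid point
    coexistence_flat_bud: np.ndarray    # (n, 2) [p_sigma, p_w] points
    coexistence_coated_coatless: np.ndarray
    spinodal: np.ndarray          # (n, 2) [p_sigma, p_w] points

    def to_frame(self):
        import pandas as pd

        rows = [
            (s, w, self.labels[i, j], self.e_min[i, j])
            for i, s in enumerate(self.p_sigma)
            for j, w in enumerate(self.p_w)
        ]
        return pd.DataFrame(rows, columns=["p_sigma", "p_w", "label", "e_min"])


def phase_diagram(
    sigma_grid: np.ndarray,
    w_grid: np.ndarray,
    p_g: float,
    curve_points: int = 101,
) -> PhaseDiagram:
    """Morphology diagram at fixed Gaussian coupling contrast.

    Labels each grid point by the global-minimum corner; locates the
    flat/bud coexistence by bracketed root finding on the corner-energy
    difference in p_sigma, the coated/coatless coexistence in p_w, and the
    spinodal (vanishing of the surface-I edge-path barrier) by bisection.
    """
    sigma_grid = np.asarray(sigma_grid, float)
    w_grid = np.asarray(w_grid, float)
    if np.any(sigma_grid < 0) or np.any(w_grid < 0):
        raise ValueError("sigma_grid and w_grid must be non-negative")
    labels = np.empty((sigma_grid.size, w_grid.size), dtype=object)
    e_min = np.zeros_like(labels, dtype=float)
    for i, ps in enumerate(sigma_grid):
        for j, pw in enumerate(w_grid):
            dp = DimensionlessParams(ps, pw, p_g, 1.0)
            corners = corner_energies(dp)
            name = min(corners, key=lambda k: corners[k].energy)
            labels[i, j] = CORNER_MORPHOLOGY[name]
            e_min[i, j] = corners[name].energy

    sig_max = float(sigma_grid.max()) if sigma_grid.size else 1.0
    w_lo, w_hi = float(w_grid.min()), float(w_grid.max())

    def flat_minus_bud(ps: float, pw: float) -> float:
        dp = DimensionlessParams(ps, pw, p_g, 1.0)
        c = corner_energies(dp)
        e_bud = min(c[CORNER_COATED].energy, c[CORNER_NECK].energy,
                    c[CORNER_MINI].energy)
        return c[CORNER_FLAT].energy - e_bud

    coex_fb = []
    for pw in np.linspace(w_lo, w_hi, curve_points):
        lo, hi = 0.0, max(sig_max, 1.0) * 4.0
        # flat is lowest at small tension, a bud at large tension
        if not (flat_minus_bud(lo, pw) < 0.0 < flat_minus_bud(hi, pw)):
            continue  # no bracket in range
        ps_star = brentq(lambda ps: flat_minus_bud(ps, pw), lo, hi,
                         xtol=1e-12, rtol=1e-12)
        coex_fb.append((ps_star, pw))

    def coated_minus_neck(pw: float) -> float:
        dp = DimensionlessParams(1.0, pw, p_g, 1.0)
        c = corner_energies(dp)
        return c[CORNER_COATED].energy - c[CORNER_NECK].energy

    coex_cc = []
    if coated_minus_neck(w_lo) * coated_minus_neck(w_hi) <= 0 and w_hi > w_lo:
        pw_star = brentq(coated_minus_neck, w_lo, w_hi, xtol=1e-12, rtol=1e-12)
        for ps in np.linspace(sigma_grid.min(), sig_max, curve_points):
            coex_cc.append((ps, pw_star))

    # The buckling barrier along the phi = 1 edge vanishes exactly when the
    # initial slope dE/dx at x = 0 turns non-positive (E' is decreasing in
    # x along this edge), which gives a sharp root for the spinodal.
    case = "I" if p_g < 2.0 else "II"

    def initial_slope(ps: float) -> float:
        dp = DimensionlessParams(ps, 0.0, p_g, 1.0)  # slope independent of p_w
        h = 1e-7
        return (cap_energy(h, 1.0, dp, case) - cap_energy(0.0, 1.0, dp, case)) / h

    spin = []
    lo, hi = 1e-6, max(sig_max, 1.0) * 8.0
    if initial_slope(lo) > 0 and initial_slope(hi) < 0:
        ps_spin = brentq(initial_slope, lo, hi, xtol=1e-12, rtol=1e-12)
        for pw in np.linspace(w_lo, w_hi, curve_points):
            spin.append((ps_spin, pw))

    return PhaseDiagram(
        p_sigma=sigma_grid, p_w=w_grid, p_g=p_g,
        labels=labels, e_min=e_min,
        coexistence_flat_bud=np.array(coex_fb).reshape(-1, 2),
        coexistence_coated_coatless=np.array(coex_cc).reshape(-1, 2),
        spinodal=np.array(spin).reshape(-1, 2),
    )


# ---------------------------------------------------------------------------
# budding pathways and the bud radius
# ---------------------------------------------------------------------------

def bud_radius(kappa: float, sigma: float) -> float:
    """Radius of the bud formed at the spinodal domain size.

    R* = 4*kappa/sigma: along the phi = 1 buckling path the energy is
    8*pi*kappa*x + 2*pi*sigma*a*sqrt(1-x) + const, whose barrier vanishes
    when the flat-disc radius reaches a_spin = 8*kappa/sigma; a sphere of
    that area has radius a_spin/2.  Set by membrane material parameters
    alone -- the origin of the narrow bud-size distributions.
    """
    if not (sigma > 0):
        raise ValueError(f"sigma must be positive, got {sigma}")
    if not (kappa > 0):
        raise ValueError(f"kappa must be positive, got {kappa}")
    return 4.0 * kappa / sigma


#: window of the Gaussian-coupling contrast for the three-stage route:
#: w*A/(4*pi) < delta_kappa_g < 2*kappa
def coupling_window(kappa: float, w: float, area: float) -> tuple[float, float]:
    return (w * area / (4.0 * np.pi), 2.0 * kappa)


@dataclass(frozen=True)
class PathwayReport:
    """Classification of the budding route for one parameter set + domain size."""

    pathway: str                  # three_stage | mini_bud | none
    stages: tuple[str, ...]
    r_coex: float                 # domain radius of flat/bud energy coexistence
    r_spin: float                 # domain radius where the barrier vanishes
    r_star: float                 # final bud radius
    barrier: float                # edge-path barrier at the given domain radius
    domain_radius: float
    notes: tuple[str, ...] = field(default=())


def budding_pathway(params: MembraneParams, domain_radius: float) -> PathwayReport:
    """Classify the budding mechanism at a given flat-domain radius.

    Three-stage route (coupling in the window w*A/4pi < dkg < 2*kappa):
    the flat ESCRT-covered domain buckles into a coated bud once the
    domain outgrows the spinodal radius, after which the ESCRTs drain into
    the neck with no barrier.  Mini-bud route (dkg > 2*kappa): the flat
    state is unstable, ESCRT-free mini-buds form spontaneously and are
    squeezed bigger by line tension provided the domain radius stays below
    sigma/w; the ESCRTs never coat the bud.  Otherwise no barrier-free
    route to the neck-localized end state exists ("none").
    """
    if not (domain_radius > 0):
        raise ValueError(f"domain_radius must be positive, got {domain_radius}")
    a = domain_radius
    area = np.pi * a * a
    scaled = MembraneParams(
        kappa=params.kappa, kappa_bar=params.kappa_bar,
        delta_kappa_g=params.delta_kappa_g, sigma=params.sigma,
        w=params.w, area_omega=area,
    )
    dp = nondimensionalize(scaled)
    kappa, dkg, sigma, w = params.kappa, params.delta_kappa_g, params.sigma, params.w
    r_coex = 4.0 * kappa / sigma
    r_spin = 8.0 * kappa / sigma
    r_star = bud_radius(kappa, sigma)
    win_lo, win_hi = coupling_window(kappa, w, area)
    notes: list[str] = []

    if dkg > win_hi:
        barrier = edge_path_barrier(dp, "II")
        squeeze_ok = (w == 0.0) or (a < sigma / w)
        stages = ("flat_unstable", "mini_bud")
        if squeeze_ok:
            stages = stages + ("coatless_bud",)
            notes.append(
                f"line tension squeezes the mini-bud to radius {a / 2.0:.6g} "
                f"(bound sigma/(2w) = {sigma / (2 * w):.6g})" if w > 0 else
                "line tension squeezes the mini-bud (w = 0: no bound)"
            )
        else:
            notes.append(
                "domain radius exceeds sigma/w; the mini-bud is not squeezed bigger"
            )
        return PathwayReport(
            pathway="mini_bud", stages=stages,
            r_coex=r_coex, r_spin=r_spin,
            r_star=min(r_star, sigma / (2 * w)) if w > 0 else r_star,
            barrier=barrier, domain_radius=a, notes=tuple(notes),
        )

    barrier = edge_path_barrier(dp, "I")
    if dkg > win_lo:
        stages = ("flat", "coated_bud", "neck_escrt_bud")
        if a < r_spin:
            notes.append(
                f"domain radius below the spinodal radius {r_spin:.6g}; "
                f"buckling requires crossing a barrier of {barrier:.6g} kappa"
            )
        return PathwayReport(
            pathway="three_stage", stages=stages,
            r_coex=r_coex, r_spin=r_spin, r_star=r_star,
            barrier=barrier, domain_radius=a, notes=tuple(notes),
        )

    notes.append(
        "coupling contrast below w*A/(4*pi): ESCRTs remain on the bud; "
        "no barrier-free route to the neck-localized state"
    )
    return PathwayReport(
        pathway="none", stages=("flat", "coated_bud"),
        r_coex=r_coex, r_spin=r_spin, r_star=r_star,
        barrier=barrier, domain_radius=a, notes=tuple(notes),
    )
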