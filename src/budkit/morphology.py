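"""Classification of minimized configurations into the three morphologies.

Minimum-energy configurations fall into three categories: flat membrane
domains (vanishing bending energy, ESCRTs and lipid domain colocalized),
ESCRT-coated buds (bending energy near 8*pi*kappa, area fraction near 1)
and coatless buds (bending energy near 8*pi*kappa, small area fraction,
ESCRTs confined to the catenoid-like neck).  The quantitative thresholds
(bending energy 0.4*kappa for "flat", area fraction 0.8 for "coated") are
package defaults calibrated once against the analytic cap-model labels;
both are arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Contour, reconstruct_contour, surface_area
from .minimizer import MinResult

#: default classification thresholds (kappa units; dimensionless fraction)
FLAT_E_BEND_MAX = 0.4
COATED_AREA_FRACTION_MIN = 0.8


@dataclass(frozen=True)
class MorphologyResult:
    """Label plus the geometric diagnostics behind it."""

    label: str                     # flat | coated_bud | coatless_bud
    area_fraction: float           # ESCRT-rich area / lipid-domain area
    cos_psi_boundary: float        # cos of tangent angle at the inner ring edge
    neck_radius: float             # min r over the ring
    neck_mean_curvature_rms: float  # rms (c1+c2)/2 over the ring
    e_bend: float                  # bending energy, kappa units


def ring_mean_curvature_rms(contour: Contour, s_a: float, s_b: float) -> float:
    """rms of the mean curvature (c1+c2)/2 over contour nodes in [s_a, s_b].

    Zero for an exact catenoid ring; ~1/rho for a spherical ring of radius
    rho.  Units: inverse contour length units.
    """
    mask = (contour.s >= s_a - 1e-12) & (contour.s <= s_b + 1e-12)
    if not np.any(mask):
        return 0.0
    h = 0.5 * (contour.c1[mask] + contour.c2[mask])
    return float(np.sqrt(np.mean(h * h)))


def classify_contour(
    contour: Contour,
    s_a: float,
    s_b: float,
    e_bend: float,
    flat_e_bend_max: float = FLAT_E_BEND_MAX,
    coated_area_fraction_min: float = COATED_AREA_FRACTION_MIN,
) -> MorphologyResult:
    """Classify a contour + ring given its bending energy in kappa units."""
    total_area = surface_area(contour)
    ring_area = surface_area(contour, max(s_a, 0.0), min(s_b, contour.s1))
    area_fraction = float(np.clip(ring_area / total_area, 0.0, 1.0))
    cos_psi_b = float(np.cos(np.interp(s_a, contour.s, contour.psi)))
    mask = (contour.s >= s_a - 1e-12) & (contour.s <= s_b + 1e-12)
    neck_radius = float(np.min(contour.r[mask])) if np.any(mask) else float("nan")
    if e_bend < flat_e_bend_max:
        label = "flat"
    elif area_fraction > coated_area_fraction_min:
        label = "coated_bud"
    else:
        label = "coatless_bud"
    return MorphologyResult(
        label=label,
        area_fraction=area_fraction,
        cos_psi_boundary=cos_psi_b,
        neck_radius=neck_radius,
        neck_mean_curvature_rms=ring_mean_curvature_rms(contour, s_a, s_b),
        e_bend=float(e_bend),
    )


def _contour_of(result: MinResult, n_nodes: int = 1025) -> Contour:
    return reconstruct_contour(result.best_profile, n_nodes)


def classify(result: MinResult, **thresholds) -> MorphologyResult:
    """Classify a converged minimization result.

    Raises if the restarts did not agree (an unconverged result could sit
    in the wrong basin, and its label would be meaningless).
    """
    if not result.converged:
        raise ValueError(
            "refusing to classify an unconverged result: restart minima "
            f"{result.restart_energies} disagree beyond tolerance"
        )
    contour = _contour_of(result)
    return classify_contour(
        contour, result.best_profile.s_a, result.best_profile.s_b,
        result.best_breakdown.e_bend, **thresholds,
    )


def boundary_tangent_angle(result: MinResult) -> float:
    """cos(psi) at the inner ESCRT-ring boundary s_a.

    The ring's outer boundary sits at the domain rim, where the tangent
    angle vanishes identically; the inner boundary is the discriminating
    one: 1 on a flat membrane (ring at the pole), 0 when it sits at a
    hemisphere's equator, near -1 for a neck-localized ring on a complete
    bud.  Changes abruptly across the coated/coatless transition.
    """
    contour = _contour_of(result)
    return float(np.cos(np.interp(result.best_profile.s_a,
                                  contour.s, contour.psi)))


def sweep_minimum(
    values,
    p_sigma: float,
    p_w: float,
    p_g: float,
    vary: str = "w",
    cfg=None,
):
    """Minimize across a 1-d parameter sweep and collect diagnostics.

    ``vary`` selects whether ``values`` replace the scaled binding
    strength (``"w"``, the default, sweeping across the coated/coatless
    transition) or the scaled line tension (``"sigma"``).  Returns a
    pandas DataFrame with columns parameter, e_min, e_bend, area_fraction,
    cos_psi, label, converged.
    """
    import pandas as pd

    from .minimizer import AnnealConfig, minimize
    from .params import DimensionlessParams

    if vary not in ("w", "sigma"):
        raise ValueError(f"vary must be 'w' or 'sigma', got {vary!r}")
    cfg = cfg or AnnealConfig()
    rows = []
    for v in np.asarray(values, float):
        ps, pw = (p_sigma, v) if vary == "w" else (v, p_w)
        dp = DimensionlessParams(ps, pw, p_g, 1.0)
        res = minimize(dp, cfg)
        morph = classify_contour(
            _contour_of(res), res.best_profile.s_a, res.best_profile.s_b,
            res.best_breakdown.e_bend,
        )
        rows.append({
            "parameter": float(v),
            "e_min": res.best_energy,
            "e_bend": morph.e_bend,
            "area_fraction": morph.area_fraction,
            "cos_psi": morph.cos_psi_boundary,
            "label": morph.label,
            "converged": res.converged,
        })
    return pd.DataFrame(rows)


def neck_catenoid_score(result: MinResult) -> float:
    """rms mean curvature over the ESCRT ring of a minimization result.

    Small values (relative to the bud's inverse radius) indicate a
    catenoid-like, minimal-surface neck.
    """
    contour = _contour_of(result)
    return ring_mean_curvature_rms(
        contour, result.best_profile.s_a, result.best_profile.s_b)
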