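"""Physical parameters of the budding model and their dimensionless form.

The energy functional is controlled by four material parameters: the mean
bending rigidity ``kappa``, the ESCRT Gaussian-coupling contrast
``delta_kappa_g`` (interpretable either as a saddle-binding coupling or as
the Gaussian-modulus contrast of the ESCRT-covered patch), the line tension
``sigma`` on the boundary of the lipid-segregated domain, and the ESCRT
binding free energy per unit area ``w``.  The uniform Gaussian modulus
``kappa_bar`` is stored for completeness but, at fixed topology, contributes
only a shape-independent additive constant and is excluded from every
minimization.  The spontaneous curvature is fixed at zero (symmetric
bilayers).

All lengths are measured internally in units of the flat-disc radius

    a = sqrt(A / pi),

where ``A`` is the area of the lipid-segregated domain Omega; energies are
measured in units of ``kappa``.  With that choice the model depends on three
dimensionless parameters only::

    p_sigma = sigma * a / kappa        (scaled line tension)
    p_w     = w * A / kappa            (scaled binding strength)
    p_g     = delta_kappa_g / kappa    (scaled Gaussian coupling)

Physical-unit I/O happens only at the CLI boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math


class ParameterError(ValueError):
    """Raised when a physical or dimensionless parameter set is invalid."""


@dataclass(frozen=True)
class MembraneParams:
    """Physical parameters of the budding energy functional.

    Parameters
    ----------
    kappa : float
        Mean bending rigidity, in energy units (e.g. multiples of kT).
    kappa_bar : float
        Uniform Gaussian bending modulus.  Constant at fixed topology and
        therefore never entering any minimization; stored for bookkeeping.
    delta_kappa_g : float
        Gaussian-coupling contrast of the ESCRT-rich patch, energy units.
    sigma : float
        Line tension acting on the outer boundary of the lipid-segregated
        domain, energy per unit length.
    w : float
        ESCRT binding free energy per unit area (positive = favorable).
    area_omega : float
        Total area A of the lipid-segregated domain Omega, length^2.
    c0 : float
        Spontaneous curvature; must be exactly zero (symmetric bilayer).
    """

    kappa: float
    delta_kappa_g: float
    sigma: float
    w: float
    area_omega: float
    kappa_bar: float = 0.0
    c0: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not (self.kappa > 0):
            raise ParameterError(f"kappa must be positive, got {self.kappa}")
        if not (self.area_omega > 0):
            raise ParameterError(
                f"area_omega must be positive, got {self.area_omega}"
            )
        if self.sigma < 0:
            raise ParameterError(f"sigma must be >= 0, got {self.sigma}")
        if self.w < 0:
            raise ParameterError(f"w must be >= 0, got {self.w}")
        if self.c0 != 0.0:
            raise ParameterError(
                f"c0 must be exactly 0 (symmetric bilayer), got {self.c0}"
            )

    @property
    def disc_radius(self) -> float:
        """Radius a = sqrt(A/pi) of the flat disc of area ``area_omega``."""
        return math.sqrt(self.area_omega / math.pi)


@dataclass(frozen=True)
class DimensionlessParams:
    """The three dimensionless parameters plus the length scale.

    ``length_scale`` is the flat-disc radius a = sqrt(A/pi) used to scale
    arc length; storing it here makes the nondimensionalization invertible
    and keeps the numeric choice in one place.
    """

    p_sigma: float
    p_w: float
    p_g: float
    length_scale: float

    def __post_init__(self) -> None:
        if self.p_sigma < 0:
            raise ParameterError(f"p_sigma must be >= 0, got {self.p_sigma}")
        if self.p_w < 0:
            raise ParameterError(f"p_w must be >= 0, got {self.p_w}")
        if not (self.length_scale > 0):
            raise ParameterError(
                f"length_scale must be positive, got {self.length_scale}"
            )

    @property
    def domain_area(self) -> float:
        """Dimensionless domain area: pi in units of length_scale^2."""
        return math.pi


def nondimensionalize(params: MembraneParams) -> DimensionlessParams:
    """Map physical parameters to the three dimensionless parameters.

    Scaling: a = sqrt(A/pi); p_sigma = sigma*a/kappa; p_w = w*A/kappa;
    p_g = delta_kappa_g/kappa.  Energies computed downstream in
    dimensionless form are the physical energies divided by kappa.
    """
    a = params.disc_radius
    return DimensionlessParams(
        p_sigma=params.sigma * a / params.kappa,
        p_w=params.w * params.area_omega / params.kappa,
        p_g=params.delta_kappa_g / params.kappa,
        length_scale=a,
    )


def redimensionalize(
    dp: DimensionlessParams, kappa: float, kappa_bar: float = 0.0
) -> MembraneParams:
    """Invert :func:`nondimensionalize` given the energy scale ``kappa``.

    The domain area is recovered from the stored length scale,
    A = pi * length_scale**2.
    """
    if not (kappa > 0):
        raise ParameterError(f"kappa must be positive, got {kappa}")
    a = dp.length_scale
    area = math.pi * a * a
    return MembraneParams(
        kappa=kappa,
        kappa_bar=kappa_bar,
        delta_kappa_g=dp.p_g * kappa,
        sigma=dp.p_sigma * kappa / a,
        w=dp.p_w * kappa / area,
        area_omega=area,
    )
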