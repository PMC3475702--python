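"""Simulated-annealing minimization of the budding energy functional.

Degrees of freedom are the Fourier amplitudes a_1..a_N of the tangent
angle and the two ESCRT-ring boundaries, held internally as fractions
(t_a, t_b) of the contour length so that the fixed-domain-area constraint
(which rescales s1) never moves the ring outside the contour.

Because psi depends on arc length only through s/s1, every energy term can
be evaluated on the unit interval: with rt(u) = int_0^u cos psi du' the
constraint 2*pi*s1^2*int_0^1 rt du = pi fixes s1 in closed form, the
bending term is scale invariant, and line/binding terms pick up the
appropriate powers of s1.  A single evaluation is a handful of small
matrix-vector products, which keeps a Metropolis anneal with tens of
thousands of moves per parameter point cheap.

Each minimization is repeated from independent initial configurations
(a flat disc and a pre-formed bud, plus random restarts) and the restart
minima are compared to flag convergence; a deterministic bounded
quasi-Newton polish sharpens each annealed minimum so that converged
restarts agree tightly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .energy import EnergyBreakdown
from .geometry import ShapeProfile
from .params import DimensionlessParams

_INVALID = 1e9  # energy assigned to inadmissible configurations


@dataclass(frozen=True)
class AnnealConfig:
    """Annealing schedule and move parameters.

    The schedule itself is an engineering choice (geometric cooling with
    move widths adapted toward ~40% acceptance); the physically meaningful
    entries are ``n_modes`` (the shape ansatz resolution) and ``restarts``
    (>= 2 independent initial configurations, compared to verify
    convergence to the global minimum).
    """

    n_modes: int = 30
    t_initial: float = 20.0
    cooling: float = 0.93
    sweeps: int = 70
    moves_per_sweep: int | None = None
    move_width_amp: float = 0.25
    move_width_boundary: float = 0.06
    seed: int = 0
    restarts: int = 2
    polish: bool = True
    n_nodes: int = 129
    convergence_tol: float = 0.5
    adapt_widths: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling < 1.0):
            raise ValueError(f"cooling factor must be in (0,1), got {self.cooling}")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if self.restarts < 2:
            raise ValueError("restarts must be >= 2 (independent initializations)")
        if self.t_initial <= 0 or self.sweeps < 1:
            raise ValueError("t_initial must be > 0 and sweeps >= 1")

    @property
    def n_dof(self) -> int:
        return self.n_modes + 2

    @property
    def moves(self) -> int:
        return self.moves_per_sweep if self.moves_per_sweep else 30 * self.n_dof


@dataclass
class MinResult:
    """Outcome of a multi-restart annealing minimization."""

    best_profile: ShapeProfile
    best_breakdown: EnergyBreakdown
    restart_energies: list[float]
    acceptance_rate: float
    converged: bool
    area_fraction: float
    dp: DimensionlessParams

    @property
    def best_energy(self) -> float:
        return self.best_breakdown.e_total


class Evaluator:
    """Fast dimensionless energy evaluation on the unit interval.

    State vector theta = [a_1..a_N, t_a, t_b].  ``parts(theta)`` returns
    (breakdown tuple, s1, area_fraction) or None for inadmissible shapes
    (negative radial coordinate or collapsed area).

    Quadrature is composite trapezoid on a uniform grid: the cumulative
    integrals for r(u) reduce to a cumulative sum, which keeps a single
    evaluation at tens of microseconds during the anneal.  Reported final
    energies are recomputed on the high-order quadrature of the energy
    module, so the trapezoid discretization only steers the search.
    """

    #: high-mode amplitude cap |a_n| <= 4*pi/n, a mild smoothness guard
    #: against self-intersecting contours during the random walk
    AMP_CAP = 4.0 * np.pi

    def __init__(self, dp: DimensionlessParams, n_modes: int, n_nodes: int = 257):
        if n_nodes % 2 == 0:
            n_nodes += 1
        self.dp = dp
        self.n_modes = n_modes
        self.u = np.linspace(0.0, 1.0, n_nodes)
        self.h = self.u[1] - self.u[0]
        n = np.arange(1, n_modes + 1)
        self.k = n * np.pi
        self.S = np.sin(np.outer(self.u, self.k))
        self.C = np.cos(np.outer(self.u, self.k))
        self._amp_cap = self.AMP_CAP / n

    def admissible(self, theta: np.ndarray) -> bool:
        a = theta[: self.n_modes]
        t_a, t_b = theta[-2], theta[-1]
        if not (0.0 <= t_a <= t_b <= 1.0):
            return False
        return bool(np.all(np.abs(a) <= self._amp_cap))

    def _cumtrapz(self, y: np.ndarray) -> np.ndarray:
        out = np.cumsum(y)
        out = self.h * (out - 0.5 * (y + y[0]))
        return out

    def parts(self, theta: np.ndarray):
        a = theta[: self.n_modes]
        t_a, t_b = theta[-2], theta[-1]
        psi = self.S @ a
        psi_u = self.C @ (a * self.k)
        cpsi = np.cos(psi)
        spsi = np.sin(psi)
        rt = self._cumtrapz(cpsi)
        if np.min(rt) < -1e-9:
            return None
        np.maximum(rt, 0.0, out=rt)
        cum_r = self._cumtrapz(rt)
        i_area = float(cum_r[-1])
        if i_area <= 1e-12:
            return None
        s1 = 1.0 / np.sqrt(2.0 * i_area)  # 2*pi*s1^2*i_area = pi
        tiny = rt < 1e-10
        c2u = np.where(tiny, psi_u, spsi / np.where(tiny, 1.0, rt))
        e_bend = float(np.pi * self.h * (
            np.sum(((psi_u + c2u) ** 2 * rt)[1:-1])
            + 0.5 * ((psi_u[-1] + c2u[-1]) ** 2 * rt[-1])
        ))
        e_line = float(2.0 * np.pi * self.dp.p_sigma * s1 * rt[-1])
        ring = float(np.interp(t_b, self.u, cum_r) - np.interp(t_a, self.u, cum_r))
        e_bind = float(-2.0 * self.dp.p_w * s1 * s1 * ring)
        psi_ab = np.sin(np.outer([t_a, t_b], self.k)) @ a
        e_gauss = float(
            2.0 * np.pi * self.dp.p_g * (np.cos(psi_ab[0]) - np.cos(psi_ab[1]))
        )
        area_fraction = ring / i_area
        return (e_bend, e_gauss, e_line, e_bind), s1, area_fraction

    def energy(self, theta: np.ndarray) -> float:
        if not self.admissible(theta):
            return _INVALID
        out = self.parts(theta)
        if out is None:
            return _INVALID
        return float(sum(out[0]))

    def bounds(self) -> list[tuple[float, float]]:
        return [(-c, c) for c in self._amp_cap] + [(0.0, 1.0), (0.0, 1.0)]


def propose_move(theta: np.ndarray, cfg: AnnealConfig, rng: np.random.Generator,
                 widths: np.ndarray | None = None) -> np.ndarray | None:
    """Perturb one randomly chosen degree of freedom by a uniform step.

    Returns the candidate state, or None when the move violates the ring
    ordering 0 <= t_a <= t_b <= 1 or the amplitude cap (rejection).
    """
    n = cfg.n_modes
    if widths is None:
        widths = np.concatenate([
            np.full(n, cfg.move_width_amp),
            [cfg.move_width_boundary, cfg.move_width_boundary],
        ])
    i = int(rng.integers(cfg.n_dof))
    cand = theta.copy()
    cand[i] += rng.uniform(-widths[i], widths[i])
    if i >= n:
        if not (0.0 <= cand[n] <= cand[n + 1] <= 1.0):
            return None
    else:
        if abs(cand[i]) > Evaluator.AMP_CAP / (i + 1):
            return None
    return cand


def _tent_bud_amplitudes(n_modes: int, n_fit: int = 201,
                         peak_u: float = 0.88, peak_psi: float = 2.85) -> np.ndarray:
    """Least-squares sine-series fit of a tent-shaped near-closed-bud psi(u)."""
    u = np.linspace(0.0, 1.0, n_fit)
    target = np.where(u <= peak_u, peak_psi * u / peak_u,
                      peak_psi * (1.0 - u) / (1.0 - peak_u))
    basis = np.sin(np.outer(u, np.arange(1, n_modes + 1) * np.pi))
    amps, *_ = np.linalg.lstsq(basis, target, rcond=None)
    cap = Evaluator.AMP_CAP / np.arange(1, n_modes + 1)
    return np.clip(amps, -cap, cap)


def _initial_state(restart: int, cfg: AnnealConfig,
                   rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_modes
    if restart == 0:  # flat disc, full ESCRT coverage
        amps = rng.normal(0.0, 0.01, n)
        return np.concatenate([amps, [0.0, 1.0]])
    if restart == 1:  # pre-formed bud with the ring near the neck
        amps = _tent_bud_amplitudes(n) + rng.normal(0.0, 0.01, n)
        return np.concatenate([amps, [0.80, 0.99]])
    amps = rng.uniform(-0.8, 0.8, n) / np.arange(1, n + 1)
    t = np.sort(rng.uniform(0.0, 1.0, 2))
    return np.concatenate([amps, t])


def _anneal_once(ev: Evaluator, cfg: AnnealConfig,
                 rng: np.random.Generator, theta0: np.ndarray):
    theta = theta0.copy()
    e_cur = ev.energy(theta)
    if e_cur >= _INVALID:  # fall back to a flat disc, always admissible
        theta = np.concatenate([np.zeros(cfg.n_modes), [0.0, 1.0]])
        e_cur = ev.energy(theta)
    best_theta, e_best = theta.copy(), e_cur
    widths = np.concatenate([
        np.full(cfg.n_modes, cfg.move_width_amp),
        [cfg.move_width_boundary, cfg.move_width_boundary],
    ])
    temp = cfg.t_initial
    n_acc = n_tot = 0
    for _ in range(cfg.sweeps):
        acc_sweep = 0
        for _ in range(cfg.moves):
            n_tot += 1
            cand = propose_move(theta, cfg, rng, widths)
            if cand is None:
                continue
            e_new = ev.energy(cand)
            if e_new >= _INVALID:  # inadmissible shapes rejected at any T
                continue
            de = e_new - e_cur
            if de <= 0.0 or rng.random() < np.exp(-de / temp):
                theta, e_cur = cand, e_new
                n_acc += 1
                acc_sweep += 1
                if e_cur < e_best:
                    best_theta, e_best = theta.copy(), e_cur
        if cfg.adapt_widths:
            rate = acc_sweep / cfg.moves
            if rate > 0.5:
                widths *= 1.15
            elif rate < 0.3:
                widths *= 0.85
            np.clip(widths, 1e-4, 2.0, out=widths)
        temp *= cfg.cooling
    return best_theta, e_best, (n_acc / max(n_tot, 1))


def _descend(ev: Evaluator, theta: np.ndarray) -> tuple[np.ndarray, float]:
    res = _scipy_minimize(
        ev.energy, theta, method="L-BFGS-B", bounds=ev.bounds(),
        options={"maxfun": 20000, "ftol": 1e-13, "gtol": 1e-9, "eps": 1e-7},
    )
    if res.fun <= ev.energy(theta):
        return np.asarray(res.x), float(res.fun)
    return theta, float(ev.energy(theta))


def _ring_candidates(ev: Evaluator, theta: np.ndarray) -> list[np.ndarray]:
    """Structured ring placements for the current shape.

    The ring position splits the landscape into basins (full coverage vs
    neck-localized); enumerate the physically relevant placements so each
    restart can compare them deterministically.
    """
    out = ev.parts(theta)
    cands = [np.concatenate([theta[:-2], [0.0, 1.0]])]
    if out is not None:
        _, _, _ = out
        psi = ev.S @ theta[: ev.n_modes]
        rt = ev._cumtrapz(np.cos(psi))
        interior = slice(ev.u.size // 3, ev.u.size - 1)
        i_neck = int(np.argmin(rt[interior])) + ev.u.size // 3
        u_neck = float(ev.u[i_neck])
        cands.append(np.concatenate([theta[:-2],
                                     [max(u_neck - 0.06, 0.0),
                                      min(u_neck + 0.06, 1.0)]]))
        cands.append(np.concatenate([theta[:-2],
                                     [max(u_neck - 0.03, 0.0), 1.0]]))
    return cands


def _canonical_states(n_modes: int) -> list[np.ndarray]:
    """Flat disc and pre-formed-bud states with full-coverage and neck rings.

    Descending from these in every restart guards against an anneal that
    failed to cross the budding barrier (the morphologies are known in
    advance from the cap model; the anneal explores everything else).
    """
    states = [np.concatenate([np.zeros(n_modes), [0.0, 1.0]])]
    for peak_u, peak_psi in ((0.80, 2.6), (0.88, 3.0), (0.92, 2.6)):
        bud = _tent_bud_amplitudes(n_modes, peak_u=peak_u, peak_psi=peak_psi)
        states.append(np.concatenate([bud, [0.0, 1.0]]))
        states.append(np.concatenate([bud, [0.82, 0.94]]))
    return states


def _polish(ev: Evaluator, theta: np.ndarray) -> tuple[np.ndarray, float]:
    """Deterministic refinement: quasi-Newton descent from the annealed
    state, from each structured ring placement, and from the canonical
    flat/bud states; best kept."""
    best_theta, best_e = _descend(ev, theta)
    for cand in _ring_candidates(ev, best_theta) + _canonical_states(ev.n_modes):
        t, e = _descend(ev, cand)
        if e < best_e:
            best_theta, best_e = t, e
    return best_theta, best_e


def minimize(dp: DimensionlessParams, cfg: AnnealConfig | None = None) -> MinResult:
    """Minimize the budding functional over shape and ring position.

    Runs ``cfg.restarts`` independent anneals from distinct initial
    configurations (flat membrane; pre-formed bud; random), keeps the
    best-ever configuration, optionally polishes each restart minimum with
    a deterministic direction-set descent, and reports whether the restart
    minima agree within ``cfg.convergence_tol`` (in units of kappa).
    """
    cfg = cfg or AnnealConfig()
    ev = Evaluator(dp, cfg.n_modes, cfg.n_nodes)
    restart_energies: list[float] = []
    thetas: list[np.ndarray] = []
    acc_rates: list[float] = []
    for restart in range(cfg.restarts):
        rng = np.random.default_rng([cfg.seed, restart])
        theta0 = _initial_state(restart, cfg, rng)
        theta, e_best, acc = _anneal_once(ev, cfg, rng, theta0)
        if cfg.polish:
            theta, e_best = _polish(ev, theta)
        restart_energies.append(e_best)
        thetas.append(theta)
        acc_rates.append(acc)
    i_best = int(np.argmin(restart_energies))
    theta_best = thetas[i_best]

    # high-order re-evaluation of the winning configuration through the
    # energy module: exact area enforcement, Simpson quadrature
    ev_fine = Evaluator(dp, cfg.n_modes, max(4 * cfg.n_nodes + 1, 1025))
    out = ev_fine.parts(theta_best)
    if out is None:
        raise RuntimeError("no admissible configuration found by the anneal")
    _, s1_coarse, area_fraction = out
    profile = ShapeProfile(
        amplitudes=theta_best[: cfg.n_modes], s1=s1_coarse,
        s_a=float(theta_best[-2]) * s1_coarse,
        s_b=float(theta_best[-1]) * s1_coarse,
    )
    from .energy import enforce_area_constraint, total_energy

    profile = enforce_area_constraint(profile)
    breakdown = total_energy(profile, dp)
    result = MinResult(
        best_profile=profile,
        best_breakdown=breakdown,
        restart_energies=restart_energies,
        acceptance_rate=float(np.mean(acc_rates)),
        converged=False,
        area_fraction=float(area_fraction),
        dp=dp,
    )
    result.converged = verify_convergence(result, cfg.convergence_tol)
    return result


def verify_convergence(result: MinResult, tol: float) -> bool:
    """True iff all restart minima lie within ``tol`` of each other."""
    if len(result.restart_energies) < 2:
        raise ValueError("convergence check needs >= 2 restarts")
    e = np.asarray(result.restart_energies)
    return bool(np.max(e) - np.min(e) <= tol)
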