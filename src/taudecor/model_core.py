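"""Mean-field equilibrium theory of two-mode Tau binding.

The microtubule surface is an ``h x p`` lattice of tubulin dimers.  Tau
binds either longitudinally (mode "p", size ``1 + sigma_p`` sites along a
protofilament) or laterally (mode "h", size ``1 + sigma_h`` sites across
protofilaments).  In the mean-field limit the equilibrium coverages
``(rho_p, rho_h)`` solve the coupled isotherms

    rho_i / (x - rho_p - rho_h) = k_eq_i * Phi_i(rho_p, rho_h),  i = p, h,

where ``Phi_i`` is the probability that one more Tau in mode i can be
inserted on the partially covered lattice — the two-dimensional analogue
of the McGhee–von Hippel large-ligand factor,

    Phi_p = A^(1+sigma_p) / (1 - sigma_p rho_p)^sigma_p,
    A = 1 - (1+sigma_p) rho_p - (1+sigma_h) rho_h,

and symmetrically for mode h.  This module solves that system, provides
the dilute-regime closed form, the insertion probabilities themselves
(both the infinite-lattice closed form and the finite-lattice gap-counting
form), the geometric gap model behind them, and the phase portraits
rho_h(rho_p) organized by kappa = k_eq_p / k_eq_h.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .params import EquilibriumCoverages, ModelParams, _norm_mode

__all__ = [
    "insertion_probability",
    "insertion_probability_general",
    "GapModel",
    "gap_model",
    "solve_equilibrium",
    "dilute_coverage",
    "portrait",
    "saturation_line",
    "SolverError",
]

# Residual tolerance on the equilibrium equations.
_RESIDUAL_TOL = 1e-10


class SolverError(RuntimeError):
    """Equilibrium solver failed to converge (diagnostics in the message)."""


# --------------------------------------------------------------------- #
# insertion probabilities


def _phi(rho_p: float, rho_h: float, sigma_p: int, sigma_h: int, mode: str) -> float:
    """Closed-form insertion probability on the infinite lattice.

    Convention for point particles (sigma = 0): (1 - sigma*rho)^sigma = 1,
    so Phi reduces to the availability A itself.
    """
    A = 1.0 - (1 + sigma_p) * rho_p - (1 + sigma_h) * rho_h
    if mode == "p":
        sigma, rho = sigma_p, rho_p
    else:
        sigma, rho = sigma_h, rho_h
    if sigma == 0:
        return A
    return A ** (1 + sigma) / (1.0 - sigma * rho) ** sigma


def insertion_probability(
    coverages: EquilibriumCoverages, params: ModelParams, mode: str
) -> float:
    """Probability Phi_mode of inserting one more Tau in ``mode``.

    Equals 1 on the empty lattice and 0 on the saturation line
    ``1 - (1+sigma_p) rho_p - (1+sigma_h) rho_h = 0``.

    Raises
    ------
    ValueError
        If the coverages lie outside the physical triangle.
    """
    mode = _norm_mode(mode)
    _check_triangle(coverages.rho_p, coverages.rho_h, params)
    phi = _phi(coverages.rho_p, coverages.rho_h, params.sigma_p, params.sigma_h, mode)
    # clip the tiny negative round-off that can occur right on the line
    return float(min(1.0, max(0.0, phi)))


def _check_triangle(rho_p: float, rho_h: float, params: ModelParams, tol=1e-12) -> None:
    if rho_p < -tol:
        raise ValueError(f"rho_p = {rho_p} violates rho_p >= 0")
    if rho_h < -tol:
        raise ValueError(f"rho_h = {rho_h} violates rho_h >= 0")
    A = 1.0 - (1 + params.sigma_p) * rho_p - (1 + params.sigma_h) * rho_h
    if A < -tol:
        raise ValueError(
            f"(rho_p, rho_h) = ({rho_p}, {rho_h}) violates the saturation "
            f"constraint 1 - (1+sigma_p) rho_p - (1+sigma_h) rho_h >= 0 (A = {A})"
        )


# --------------------------------------------------------------------- #
# gap model


@dataclass(frozen=True)
class GapModel:
    """Geometric nearest-gap model along one lattice direction.

    On a line in direction k the bound Taus form a one-dimensional
    arrangement of particles with density ``rho_dir`` (particles per
    site counted along that line) separated by gaps of g empty sites,
    ``g = 0, 1, 2, ...``, distributed geometrically:

        f_k(g) = (1 - u_k) u_k^g,
        u_par  = A / (1 - sigma_p rho_p),
        u_perp = A / (1 - sigma_h rho_h).

    ``empty_lattice`` flags the degenerate no-particle state (u -> 1,
    gaps undefined); the pmf is then unavailable.
    """

    direction: str
    u: float
    rho_dir: float
    empty_lattice: bool = False

    def pmf(self, g) -> np.ndarray:
        """f_k(g) for integer gap sizes g >= 0."""
        if self.empty_lattice:
            raise ValueError(
                "gap distribution undefined on the empty lattice (no particles)"
            )
        g = np.asarray(g)
        out = np.where(g >= 0, (1.0 - self.u) * self.u ** np.maximum(g, 0), 0.0)
        return out if out.ndim else float(out)


def _norm_direction(direction: str) -> str:
    d = str(direction).lower()
    aliases = {
        "parallel": "parallel", "par": "parallel", "∥": "parallel",
        "perp": "perp", "perpendicular": "perp", "⊥": "perp",
    }
    if d not in aliases:
        raise ValueError(f"direction must be 'parallel' or 'perp', got {direction!r}")
    return aliases[d]


def gap_model(
    coverages: EquilibriumCoverages, params: ModelParams, direction: str
) -> GapModel:
    """Geometric gap distribution along ``direction`` in {parallel, perp}.

    The parallel direction runs along a protofilament (where p-mode Taus
    extend and h-mode Taus project onto single sites); perp runs along
    the helix.  Saturated input yields u = 0 (all gaps of size 0).
    """
    direction = _norm_direction(direction)
    _check_triangle(coverages.rho_p, coverages.rho_h, params)
    sp, sh = params.sigma_p, params.sigma_h
    rho_p, rho_h = coverages.rho_p, coverages.rho_h
    A = coverages.availability
    if direction == "parallel":
        denom = 1.0 - sp * rho_p
        rho_dir = rho_p + (1 + sh) * rho_h
    else:
        denom = 1.0 - sh * rho_h
        rho_dir = (1 + sp) * rho_p + rho_h
    if rho_dir <= 0.0:
        return GapModel(direction=direction, u=1.0, rho_dir=0.0, empty_lattice=True)
    u = max(0.0, A / denom)
    return GapModel(direction=direction, u=u, rho_dir=rho_dir)


def _direction_of_mode(mode: str) -> str:
    # a p-mode Tau is inserted along a protofilament line, an h-mode Tau
    # along a helix line
    return "parallel" if mode == "p" else "perp"


def insertion_probability_general(
    coverages: EquilibriumCoverages,
    params: ModelParams,
    mode: str,
    lattice_length: float,
    gap_pmf: Sequence[float] | None = None,
) -> float:
    """Finite-lattice insertion probability by gap counting.

    A particle of size ``1 + sigma`` fits into a gap of g empty sites in
    ``g - sigma`` ways (for g >= 1 + sigma), so on a line of length
    ``ell`` holding ``n = rho_dir * ell`` particles (hence n + 1 gaps)

        Phi = (rho_dir + 1/ell) * sum_{g=1+sigma}^{g_max} (g - sigma) f(g).

    With the geometric gap model this converges to the closed-form
    ``insertion_probability`` as ell -> infinity; passing
    ``lattice_length=numpy.inf`` evaluates the infinite-lattice gap sum
    ``rho_dir * u^(1+sigma) / (1 - u)`` directly, which reproduces the
    closed form to round-off.  ``gap_pmf`` may supply an explicit gap
    distribution (index = gap size); it must be normalized.  The maximum
    gap is capped at the total empty length ``g_max = floor(A * ell)``.
    """
    mode = _norm_mode(mode)
    if lattice_length < 1:
        raise ValueError("lattice_length must be >= 1")
    sigma = params.sigma(mode)
    gm = gap_model(coverages, params, _direction_of_mode(mode))
    if np.isinf(lattice_length):
        if gap_pmf is not None:
            raise ValueError("an explicit gap_pmf requires a finite lattice_length")
        if gm.empty_lattice:
            return 1.0
        u = gm.u
        return 0.0 if u in (0.0, 1.0) else float(gm.rho_dir * u ** (1 + sigma) / (1.0 - u))
    ell = float(lattice_length)
    g_max = int(np.floor(coverages.availability * ell + 1e-9))
    if gap_pmf is not None:
        f = np.asarray(gap_pmf, dtype=float)
        if f.ndim != 1 or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("gap_pmf must be a normalized 1-D probability vector")
        g = np.arange(f.size)
        weights = np.clip(g - sigma, 0, None) * (g >= 1 + sigma)
        s = float(np.sum(weights * f))
        return float((gm.rho_dir + 1.0 / ell) * s)
    if gm.empty_lattice:
        # single gap of size ell: one particle fits in ell - sigma ways
        return max(0.0, (1.0 / ell) * (ell - sigma))
    u = gm.u
    if u == 0.0:
        return 0.0
    # partial geometric sum: sum_{m=1}^{M} m (1-u) u^(sigma+m), M = g_max - sigma
    M = g_max - sigma
    if M <= 0:
        return 0.0
    s = u ** (sigma + 1) * (1.0 - (M + 1) * u**M + M * u ** (M + 1)) / (1.0 - u)
    return float((gm.rho_dir + 1.0 / ell) * s)


# --------------------------------------------------------------------- #
# equilibrium solver


def _residuals(rho_p, rho_h, params: ModelParams) -> np.ndarray:
    """F_i = rho_i - (x - rho) k_i Phi_i for the active modes (0 otherwise)."""
    x = params.x
    free = x - rho_p - rho_h
    fp = rho_p - free * params.k_eq_p * _phi(
        rho_p, rho_h, params.sigma_p, params.sigma_h, "p"
    )
    fh = rho_h - free * params.k_eq_h * _phi(
        rho_p, rho_h, params.sigma_p, params.sigma_h, "h"
    )
    return np.array([fp, fh])


def _jacobian(rho_p, rho_h, params: ModelParams) -> np.ndarray:
    sp, sh = params.sigma_p, params.sigma_h
    A = 1.0 - (1 + sp) * rho_p - (1 + sh) * rho_h
    Bp = 1.0 - sp * rho_p
    Bh = 1.0 - sh * rho_h
    x = params.x
    free = x - rho_p - rho_h

    phi_p = _phi(rho_p, rho_h, sp, sh, "p")
    phi_h = _phi(rho_p, rho_h, sp, sh, "h")
    # dPhi_p/drho_p, dPhi_p/drho_h
    dpp = -((1 + sp) ** 2) * A**sp / Bp**sp + sp**2 * A ** (1 + sp) / Bp ** (sp + 1)
    dph = -(1 + sp) * (1 + sh) * A**sp / Bp**sp
    dhh = -((1 + sh) ** 2) * A**sh / Bh**sh + sh**2 * A ** (1 + sh) / Bh ** (sh + 1)
    dhp = -(1 + sh) * (1 + sp) * A**sh / Bh**sh

    kp, kh = params.k_eq_p, params.k_eq_h
    j11 = 1.0 + kp * phi_p - free * kp * dpp
    j12 = kp * phi_p - free * kp * dph
    j21 = kh * phi_h - free * kh * dhp
    j22 = 1.0 + kh * phi_h - free * kh * dhh
    return np.array([[j11, j12], [j21, j22]])


def _solve_single_mode(params: ModelParams, mode: str) -> float:
    """Bracketed 1-D solve of rho = (x - rho) k Phi(rho) for one active mode."""
    sigma = params.sigma(mode)
    k = params.k_eq(mode)
    x = params.x
    rho_sat = 1.0 / (1 + sigma)

    def g(rho):
        if mode == "p":
            phi = _phi(rho, 0.0, params.sigma_p, params.sigma_h, "p")
        else:
            phi = _phi(0.0, rho, params.sigma_p, params.sigma_h, "h")
        return rho - (x - rho) * k * phi

    hi = min(x, rho_sat)
    # g(0) = -x k < 0; g(hi) > 0 (either no free Tau left or Phi -> 0)
    hi_eval = hi * (1.0 - 1e-15)
    if g(hi_eval) <= 0:  # pragma: no cover - saturated corner round-off
        return hi_eval
    rho = brentq(g, 0.0, hi_eval, xtol=1e-16, rtol=8.9e-16, maxiter=200)
    return float(rho)


def _newton_two_mode(
    params: ModelParams, guess: tuple[float, float], max_iter: int = 80
) -> tuple[float, float] | None:
    """Damped Newton restricted to the open triangle; None on failure."""
    sp, sh = params.sigma_p, params.sigma_h
    rho_p, rho_h = guess

    def inside(a, b):
        return (
            a > 0.0
            and b > 0.0
            and 1.0 - (1 + sp) * a - (1 + sh) * b > 0.0
            and params.x - a - b > 0.0
        )

    if not inside(rho_p, rho_h):
        return None
    f = _residuals(rho_p, rho_h, params)
    norm = np.max(np.abs(f))
    for _ in range(max_iter):
        if norm < 1e-13:
            return rho_p, rho_h
        J = _jacobian(rho_p, rho_h, params)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return None
        alpha = 1.0
        for _ in range(60):
            a = rho_p + alpha * step[0]
            b = rho_h + alpha * step[1]
            if inside(a, b):
                f_new = _residuals(a, b, params)
                n_new = np.max(np.abs(f_new))
                if n_new < norm:
                    rho_p, rho_h, f, norm = a, b, f_new, n_new
                    break
            alpha *= 0.5
        else:
            # line search exhausted: near-saturation systems bottom out on
            # the round-off floor of A = 1 - (1+s_p)r_p - (1+s_h)r_h well
            # below the 1e-10 tolerance — accept if already there
            return (rho_p, rho_h) if norm < _RESIDUAL_TOL else None
    return (rho_p, rho_h) if norm < _RESIDUAL_TOL else None


def _rho_p_given_rh(rho_h: float, params: ModelParams) -> float:
    """Unique root of the p-mode isotherm at fixed rho_h (bracketed 1-D)."""
    sp, sh = params.sigma_p, params.sigma_h
    kp = params.k_eq_p
    x = params.x
    top = min(x - rho_h, (1.0 - (1 + sh) * rho_h) / (1 + sp))
    if top <= 0.0:
        return 0.0

    def f(rp):
        return rp - (x - rp - rho_h) * kp * _phi(rp, rho_h, sp, sh, "p")

    hi = top * (1.0 - 1e-14)
    if f(hi) <= 0:  # pragma: no cover - saturated corner round-off
        return hi
    return brentq(f, 0.0, hi, xtol=1e-16, rtol=8.9e-16, maxiter=200)


def _two_mode_roots(params: ModelParams, n_scan: int = 400) -> list[tuple[float, float]]:
    """All equilibria of the coupled system by 1-D reduction.

    For each rho_h the p-mode equation has a unique root rho_p*(rho_h)
    (its two sides are monotone in opposite directions), reducing the
    system to a scalar equation in rho_h that is scanned for sign
    changes.  With unequal binding sizes the system can be genuinely
    multistable (up to three roots around a fold), so every root is
    returned.
    """
    sh = params.sigma_h
    kh = params.k_eq_h
    x = params.x

    def H(rh):
        rp = _rho_p_given_rh(rh, params)
        return rh - (x - rp - rh) * kh * _phi(rp, rh, params.sigma_p, sh, "h")

    ub = min(x, 1.0 / (1 + sh)) * (1.0 - 1e-12)
    grid = np.linspace(0.0, ub, n_scan)
    vals = np.array([H(r) for r in grid])
    roots = []
    for i in np.nonzero(np.diff(np.sign(vals)) != 0)[0]:
        rh = brentq(H, grid[i], grid[i + 1], xtol=1e-16, rtol=8.9e-16, maxiter=200)
        rp = _rho_p_given_rh(rh, params)
        polished = _newton_two_mode(params, (rp, rh), max_iter=30)
        roots.append(polished if polished is not None else (rp, rh))
    # deduplicate near-identical roots from grid-edge sign flickers
    unique = []
    for r in roots:
        if all(abs(r[0] - u[0]) + abs(r[1] - u[1]) > 1e-9 for u in unique):
            unique.append(r)
    return unique


def _select_by_relaxation(
    params: ModelParams, roots: list[tuple[float, float]]
) -> tuple[float, float]:
    """Pick the equilibrium reached by the adsorption dynamics from an
    empty lattice (the attractor of d(rho)/dt = -F from the origin)."""
    from scipy.integrate import solve_ivp

    def rhs(_t, y):
        return -_residuals(y[0], y[1], params)

    t_end = 200.0 * (1.0 + 1.0 / max(params.k_eff, 1e-3))
    sol = solve_ivp(
        rhs, (0.0, t_end), [1e-12, 1e-12], method="LSODA", rtol=1e-10, atol=1e-14
    )
    end = sol.y[:, -1]
    dists = [abs(end[0] - r[0]) + abs(end[1] - r[1]) for r in roots]
    return roots[int(np.argmin(dists))]


def solve_equilibrium(params: ModelParams) -> EquilibriumCoverages:
    """Solve the coupled equilibrium isotherms for (rho_p, rho_h).

    An inactive mode (k_eq = 0) is pinned at exactly 0 and the remaining
    equation solved by bracketed bisection.  The two-mode system is
    reduced to one dimension (the p-mode equation is solved exactly for
    every trial rho_h), scanned for all roots, and each root polished by
    a damped Newton iteration.  When several equilibria coexist — which
    happens for unequal binding sizes near a fold — the one dynamically
    selected from the empty lattice is returned.

    Raises
    ------
    SolverError
        If no solution with residual below 1e-10 is found.
    """
    if params.k_eq_h == 0:
        rho_p = _solve_single_mode(params, "p")
        res = np.max(np.abs(_residuals(rho_p, 0.0, params)))
        return EquilibriumCoverages.from_rhos(rho_p, 0.0, params, residual=res)
    if params.k_eq_p == 0:
        rho_h = _solve_single_mode(params, "h")
        res = np.max(np.abs(_residuals(0.0, rho_h, params)))
        return EquilibriumCoverages.from_rhos(0.0, rho_h, params, residual=res)

    roots = _two_mode_roots(params)
    if not roots:
        raise SolverError(
            f"equilibrium solver found no root for {params.to_dict()} "
            "(scalar-reduction scan returned no sign change)"
        )
    sol = roots[0] if len(roots) == 1 else _select_by_relaxation(params, roots)
    res = np.max(np.abs(_residuals(*sol, params)))
    if res > _RESIDUAL_TOL:
        raise SolverError(
            f"equilibrium residual {res:.3e} exceeds 1e-10 for {params.to_dict()}"
        )
    return EquilibriumCoverages.from_rhos(sol[0], sol[1], params, residual=res)


# --------------------------------------------------------------------- #
# dilute closed form


def dilute_coverage(params: ModelParams, mode: str) -> float:
    """Single-mode dilute-regime closed form for the total coverage.

    rho = (1/2) [ (a + x) - sqrt((a + x)^2 - 4x/(1+2 sigma)) ],
    a = (1 + 1/k_eq) / (1 + 2 sigma).

    Exact in the dilute limit; agrees with the full solver to <1% for
    rho <~ 0.05.
    """
    mode = _norm_mode(mode)
    sigma = params.sigma(mode)
    k = params.k_eq(mode)
    if k <= 0:
        raise ValueError(f"mode {mode!r} is inactive (k_eq = 0)")
    x = params.x
    a = (1.0 + 1.0 / k) / (1.0 + 2 * sigma)
    disc = (a + x) ** 2 - 4.0 * x / (1.0 + 2 * sigma)
    return float(0.5 * ((a + x) - np.sqrt(max(disc, 0.0))))


# --------------------------------------------------------------------- #
# saturation line and phase portraits


def saturation_line(params: ModelParams) -> Callable[[float], float]:
    """Map rho_p -> rho_h on the saturation line, clipped to the triangle."""
    sp, sh = params.sigma_p, params.sigma_h

    def line(rho_p):
        rho_p = np.asarray(rho_p, dtype=float)
        rho_h = (1.0 - (1 + sp) * rho_p) / (1 + sh)
        out = np.clip(rho_h, 0.0, 1.0 / (1 + sh))
        return out if out.ndim else float(out)

    return line


def _portrait_residual(rho_p, rho_h, sp, sh, kappa):
    """Polynomial form of the portrait relation (ratio of the two isotherms).

    R = rho_p (1 - sigma_p rho_p)^sigma_p
        - kappa rho_h (1 - sigma_h rho_h)^sigma_h A^(sigma_p - sigma_h),
    zero along the coverage trajectory, well defined on the boundary.
    """
    A = 1.0 - (1 + sp) * rho_p - (1 + sh) * rho_h
    d = sp - sh
    if d >= 0:
        return rho_p * (1.0 - sp * rho_p) ** sp - kappa * rho_h * (
            1.0 - sh * rho_h
        ) ** sh * A**d
    # multiply through by A^(sh - sp) to keep the expression polynomial
    return rho_p * (1.0 - sp * rho_p) ** sp * A ** (-d) - kappa * rho_h * (
        1.0 - sh * rho_h
    ) ** sh


def _portrait_endpoint(params: ModelParams, kappa: float) -> tuple[float, float]:
    """Intersection of the portrait with the saturation boundary."""
    sp, sh = params.sigma_p, params.sigma_h
    if sp > sh:
        return 0.0, 1.0 / (1 + sh)
    if sp < sh:
        return 1.0 / (1 + sp), 0.0
    # equal sizes: solve on the saturation line A = 0 (the A^0 factor drops)
    line = saturation_line(params)

    def g(rho_p):
        rho_h = (1.0 - (1 + sp) * rho_p) / (1 + sh)
        return rho_p * (1.0 - sp * rho_p) ** sp - kappa * rho_h * (1.0 - sh * rho_h) ** sh

    lo, hi = 0.0, 1.0 / (1 + sp)
    rho_p = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16)
    return float(rho_p), float(line(rho_p))


def portrait(params: ModelParams, n_points: int = 200) -> np.ndarray:
    """Trace the coverage trajectory rho_h vs rho_p for kappa = k_eq_p/k_eq_h.

    Returns an (n_points, 2) array of (rho_p, rho_h) from (0, 0) to the
    saturation boundary, traced by pseudo-arclength continuation (the
    curve is bi-valued in rho_p when sigma_p != sigma_h, so a pointwise
    rho_h(rho_p) solve would lose the upper branch).  Interior points
    satisfy the portrait relation to residual < 1e-10.  Degenerate kappa
    (0 or inf) returns the corresponding axis segment.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    sp, sh = params.sigma_p, params.sigma_h
    kappa = params.kappa
    if kappa == 0.0:
        rho_h = np.linspace(0.0, 1.0 / (1 + sh), n_points)
        return np.column_stack([np.zeros(n_points), rho_h])
    if np.isinf(kappa):
        rho_p = np.linspace(0.0, 1.0 / (1 + sp), n_points)
        return np.column_stack([rho_p, np.zeros(n_points)])

    end = _portrait_endpoint(params, kappa)
    dense = _trace_portrait(sp, sh, kappa, end)
    # resample n_points by arc length, correcting each back onto the curve
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], n_points)
    pts = np.empty((n_points, 2))
    pts[0] = dense[0]
    pts[-1] = end
    for m in range(1, n_points - 1):
        idx = int(np.searchsorted(s, targets[m]))
        idx = min(max(idx, 1), len(dense) - 1)
        w = (targets[m] - s[idx - 1]) / max(s[idx] - s[idx - 1], 1e-300)
        q = (1 - w) * dense[idx - 1] + w * dense[idx]
        pts[m] = _project_onto_portrait(q, sp, sh, kappa)
    return pts


def _grad_residual(q, sp, sh, kappa, eps=1e-8):
    g = np.empty(2)
    for d in range(2):
        e = np.zeros(2)
        e[d] = eps
        g[d] = (
            _portrait_residual(*(q + e), sp, sh, kappa)
            - _portrait_residual(*(q - e), sp, sh, kappa)
        ) / (2 * eps)
    return g


def _project_onto_portrait(q, sp, sh, kappa, tol=1e-13):
    """Newton correction along the residual gradient back onto the curve."""
    q = np.array(q, dtype=float)
    for _ in range(50):
        r = _portrait_residual(*q, sp, sh, kappa)
        if abs(r) < tol:
            break
        g = _grad_residual(q, sp, sh, kappa)
        gn = g @ g
        if gn == 0.0:
            break
        q = q - r * g / gn
        q = np.clip(q, 0.0, [1.0 / (1 + sp), 1.0 / (1 + sh)])
    return q


def _trace_portrait(sp, sh, kappa, end, ds=2e-3) -> np.ndarray:
    """Pseudo-arclength trace of the portrait from the origin to ``end``."""
    pts = [np.array([0.0, 0.0])]
    # near the origin A ~ 1 and the relation linearizes to rho_p = kappa rho_h
    t0 = np.array([kappa, 1.0])
    t0 /= np.linalg.norm(t0)
    q = _project_onto_portrait(pts[0] + 1e-6 * t0, sp, sh, kappa)
    pts.append(q)
    prev_dir = t0
    end = np.asarray(end)
    for _ in range(20000):
        q = pts[-1]
        if np.linalg.norm(q - end) < 1.5 * ds:
            break
        g = _grad_residual(q, sp, sh, kappa)
        tang = np.array([-g[1], g[0]])
        n = np.linalg.norm(tang)
        if n == 0.0:
            break
        tang /= n
        if tang @ prev_dir < 0:
            tang = -tang
        q_new = _project_onto_portrait(q + ds * tang, sp, sh, kappa)
        step = q_new - q
        if np.linalg.norm(step) < 1e-12:
            break
        prev_dir = step / np.linalg.norm(step)
        pts.append(q_new)
    pts.append(end.astype(float))
    return np.array(pts)
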