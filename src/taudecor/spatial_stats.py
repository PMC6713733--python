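"""Nearest-neighbor spacing statistics of bound Tau molecules.

Along each lattice direction k (parallel = along a protofilament,
perp = along the helix) the bound Taus form a one-dimensional point
process whose nearest-neighbor center-to-center distance r (in 8 nm
site units) is distributed as a mixture of shifted geometric laws:

    P_k(r)    = sum_ij z_k,i z_k,j P_k,ij(r),
    P_k,ij(r) = (1 - u_k) u_k^(r - r_k,ij),  r - r_k,ij = 0, 1, 2, ...

The shift r_k,ij is the close-packing distance between a Tau bound in
mode i and one in mode j; mixed p-h pairs pack at the half-integer
distance 1 + sigma_k/2, which is why the distributions live on a grid
with step 0.5.  The weights z_k,i follow from the directional coverages
rho_k,i (an h-mode Tau crosses 1 + sigma_h protofilament lines, so it is
counted (1 + sigma_h) times along the parallel direction, and vice
versa).  Only the long-lattice limit (h, p >> 1) is exposed here: the
finite-lattice corrections are O(1/h) and invisible at microtubule
dimensions.

The center convention matches the close-packing matrix: a p-mode Tau
anchored at site i (size sigma_p) has its center at i + sigma_p/2 on its
protofilament line, while an h-mode Tau occupies a single site on any
protofilament line it crosses (center at that site); symmetrically along
the helix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import _norm_direction, gap_model
from .params import EquilibriumCoverages, ModelParams, _norm_mode

__all__ = [
    "SpacingDistribution",
    "directional_coverages",
    "close_packing_matrix",
    "spacing_distribution",
    "single_mode_spacing",
    "mean_spacing",
    "order_parameter",
]

_MODES = ("p", "h")
# Truncation of the r grid: 1e-13 retained-mass tolerance, comfortably
# beyond the 1e-9 guarantee, so that first moments of the truncated pmf
# match the closed-form means to ~1e-8 even at near-unit u.
_MASS_TOL = 1e-13


def directional_coverages(
    coverages: EquilibriumCoverages, params: ModelParams
) -> dict[tuple[str, str], float]:
    """Directional coverages rho_k,i (particles per site along direction k).

    Keys are (direction, mode).  Along the parallel direction each h-mode
    Tau appears on 1 + sigma_h protofilament lines, hence
    rho_par,h = (1 + sigma_h) rho_h while rho_par,p = rho_p; symmetrically
    for the perpendicular (helix) direction.
    """
    sp, sh = params.sigma_p, params.sigma_h
    return {
        ("parallel", "p"): coverages.rho_p,
        ("parallel", "h"): (1 + sh) * coverages.rho_h,
        ("perp", "p"): (1 + sp) * coverages.rho_p,
        ("perp", "h"): coverages.rho_h,
    }


def close_packing_matrix(params: ModelParams, direction: str) -> np.ndarray:
    """2x2 matrix of close-packing center-to-center distances r_k,ij.

    Index order (p, h).  Along the parallel direction two p-mode Taus
    pack at 1 + sigma_p, two h-mode Taus at 1 (they occupy single sites
    on each line), and a mixed pair at 1 + sigma_p/2; the perpendicular
    matrix swaps the roles (with sigma_h in the off-diagonal).
    """
    direction = _norm_direction(direction)
    sp, sh = params.sigma_p, params.sigma_h
    if direction == "parallel":
        off = 1.0 + sp / 2.0
        return np.array([[1.0 + sp, off], [off, 1.0]])
    off = 1.0 + sh / 2.0
    return np.array([[1.0, off], [off, 1.0 + sh]])


@dataclass(frozen=True)
class SpacingDistribution:
    """Discrete nearest-neighbor distance distribution along one direction.

    ``r_grid`` is in site units (step 0.5; multiply by ``site_length_nm``
    for nm).  ``component_pmfs[i, j]`` holds P_k,ij aligned on the grid,
    ``weights`` the (z_p, z_h) mode fractions counted along the
    direction, and ``total_pmf = sum_ij z_i z_j P_k,ij``.
    """

    direction: str
    r_grid: np.ndarray
    total_pmf: np.ndarray
    component_pmfs: np.ndarray  # shape (2, 2, len(r_grid)), order (p, h)
    weights: tuple[float, float]
    close_packing: np.ndarray
    u: float
    site_length_nm: float

    @property
    def r_nm(self) -> np.ndarray:
        return self.r_grid * self.site_length_nm

    def mean(self) -> float:
        """First moment of the total pmf, in site units."""
        return float(np.sum(self.r_grid * self.total_pmf))

    def pmf_at(self, r: float) -> float:
        """Total probability at distance r (0 if off the support)."""
        idx = np.nonzero(np.isclose(self.r_grid, r, atol=1e-9))[0]
        return float(self.total_pmf[idx[0]]) if idx.size else 0.0

    def pmf_on_grid(self, r_values, renormalize: bool = False) -> np.ndarray:
        """Total pmf evaluated on an arbitrary r grid.

        With ``renormalize=True`` the values are rescaled to sum to 1
        over the given grid — the correct reference when comparing with
        an empirical histogram that was itself truncated to that window.
        """
        vals = np.array([self.pmf_at(float(r)) for r in np.asarray(r_values)])
        if renormalize:
            s = vals.sum()
            if s <= 0:
                raise ValueError("no probability mass on the requested grid")
            vals = vals / s
        return vals

    def component_at(self, i: str, j: str, r: float) -> float:
        a, b = _MODES.index(_norm_mode(i)), _MODES.index(_norm_mode(j))
        idx = np.nonzero(np.isclose(self.r_grid, r, atol=1e-9))[0]
        return float(self.component_pmfs[a, b, idx[0]]) if idx.size else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_sites": self.r_grid,
                "r_nm": self.r_nm,
                "P_total": self.total_pmf,
                "P_pp": self.component_pmfs[0, 0],
                "P_ph": self.component_pmfs[0, 1],
                "P_hp": self.component_pmfs[1, 0],
                "P_hh": self.component_pmfs[1, 1],
            }
        )


def spacing_distribution(
    coverages: EquilibriumCoverages, params: ModelParams, direction: str
) -> SpacingDistribution:
    """Nearest-neighbor distance distribution P_k(r) along ``direction``.

    Each component is a geometric law with ratio u_k (from the gap model)
    shifted to its close-packing distance; the grid is truncated once
    every component retains all but ~1e-13 of its mass.  At saturation
    (u_k = 0) the components collapse to Kronecker deltas at r_k,ij.

    Raises
    ------
    ValueError
        If no Tau is bound (empty lattice has no neighbor distances).
    """
    direction = _norm_direction(direction)
    gm = gap_model(coverages, params, direction)
    if gm.empty_lattice:
        raise ValueError("no bound Tau: spacing distribution undefined on an empty lattice")
    u = gm.u
    rcp = close_packing_matrix(params, direction)
    dcov = directional_coverages(coverages, params)
    rho_dir = dcov[(direction, "p")] + dcov[(direction, "h")]
    z_p = dcov[(direction, "p")] / rho_dir
    z_h = 1.0 - z_p

    # number of geometric terms needed for the mass tolerance
    if u > 0.0:
        n_tail = int(np.ceil(np.log(_MASS_TOL) / np.log(u))) + 1
    else:
        n_tail = 1
    r_min = float(rcp.min())
    r_max = float(rcp.max()) + (n_tail - 1)
    n_grid = int(round((r_max - r_min) / 0.5)) + 1
    r_grid = r_min + 0.5 * np.arange(n_grid)

    comps = np.zeros((2, 2, n_grid))
    for a in range(2):
        for b in range(2):
            offsets = rcp[a, b] + np.arange(n_tail)
            idx = np.round((offsets - r_min) / 0.5).astype(int)
            keep = idx < n_grid
            if u > 0.0:
                pmf = (1.0 - u) * u ** np.arange(n_tail)
            else:
                pmf = np.zeros(n_tail)
                pmf[0] = 1.0
            comps[a, b, idx[keep]] = pmf[keep]

    z = np.array([z_p, z_h])
    total = np.einsum("a,b,abr->r", z, z, comps)
    return SpacingDistribution(
        direction=direction,
        r_grid=r_grid,
        total_pmf=total,
        component_pmfs=comps,
        weights=(float(z_p), float(z_h)),
        close_packing=rcp,
        u=float(u),
        site_length_nm=params.site_length_nm,
    )


def single_mode_spacing(rho: float, params: ModelParams, mode: str) -> SpacingDistribution:
    """Parallel-direction spacing distribution when only ``mode`` binds.

    Mode p: P(r) = rho/(1 - sigma_p rho) * u^(r - (1+sigma_p)) with
    u = (1 - (1+sigma_p) rho)/(1 - sigma_p rho), support starting at the
    close packing 1 + sigma_p.  Mode h: P(r) =
    (1+sigma_h) rho [1 - (1+sigma_h) rho]^(r-1), support r = 1, 2, ...
    Identical to ``spacing_distribution`` with the other coverage zero.
    """
    mode = _norm_mode(mode)
    sigma = params.sigma(mode)
    if not 0.0 < rho <= 1.0 / (1 + sigma):
        raise ValueError(
            f"rho must lie in (0, 1/(1+sigma)] = (0, {1.0/(1+sigma)}], got {rho}"
        )
    rho_p, rho_h = (rho, 0.0) if mode == "p" else (0.0, rho)
    cov = EquilibriumCoverages.from_rhos(rho_p, rho_h, params)
    return spacing_distribution(cov, params, "parallel")


def mean_spacing(
    coverages: EquilibriumCoverages, params: ModelParams, direction: str
) -> tuple[float, float]:
    """Mean nearest-neighbor distance along ``direction``.

    Returns ``(sites, nm)``.  The closed form is the geometric mean gap
    plus the coverage-weighted close packing,

        <r_k> = u_k/(1 - u_k) + sum_ij z_i z_j r_k,ij,

    which reduces to 1/rho (mode p) and 1/((1+sigma_h) rho) (mode h) in
    the single-mode limits, and to 1/(1 - sigma rho_s) at saturation.
    """
    direction = _norm_direction(direction)
    gm = gap_model(coverages, params, direction)
    if gm.empty_lattice:
        raise ValueError("no bound Tau: mean spacing undefined on an empty lattice")
    dcov = directional_coverages(coverages, params)
    rho_dir = dcov[(direction, "p")] + dcov[(direction, "h")]
    z = np.array([dcov[(direction, "p")] / rho_dir, dcov[(direction, "h")] / rho_dir])
    rcp = close_packing_matrix(params, direction)
    mean_sites = gm.u / (1.0 - gm.u) + float(z @ rcp @ z)
    return float(mean_sites), float(mean_sites * params.site_length_nm)


def order_parameter(coverages: EquilibriumCoverages, params: ModelParams) -> float:
    """Alignment order parameter S = (1+sigma_p) rho_p - (1+sigma_h) rho_h.

    S = +1 for a lattice saturated with longitudinal (p) Taus, -1 for
    lateral (h) saturation, 0 for the balanced 50-50 decoration.
    """
    return (
        (1 + params.sigma_p) * coverages.rho_p
        - (1 + params.sigma_h) * coverages.rho_h
    )
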