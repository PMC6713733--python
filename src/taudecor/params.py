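"""Parameter containers for the two-mode Tau/microtubule decoration model.

A Tau molecule binds the microtubule outer surface either longitudinally
along a protofilament ("p" mode, covering ``1 + sigma_p`` tubulin dimers)
or laterally across adjacent protofilaments ("h" mode, covering
``1 + sigma_h`` dimers).  At equilibrium the decoration is controlled by
five parameters: the two binding sizes ``sigma_p`` and ``sigma_h``, the two
dimensionless equilibrium constants ``k_eq_p = N[MT]/K_d,p`` and
``k_eq_h = N[MT]/K_d,h``, and the Tau:tubulin-dimer ratio
``x = [Tau]/(N [MT])``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParams",
    "EquilibriumCoverages",
    "PhysiologicalRangeWarning",
    "SITE_LENGTH_NM",
]

#: Length of one binding site (an alpha-beta tubulin dimer) in nanometres.
SITE_LENGTH_NM = 8.0

# Axonal ranges used only to emit advisory warnings, never hard errors:
# the model is mathematically valid outside them.
_X_RANGE = (0.1, 10.0)
_KEFF_RANGE = (0.1, 1.0e3)


class PhysiologicalRangeWarning(UserWarning):
    """Parameters lie outside the estimated axonal ranges."""


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the decoration model.

    Parameters
    ----------
    sigma_p, sigma_h : int
        Extra sites covered by a Tau bound in the longitudinal (p) and
        lateral (h) mode; the corresponding stoichiometry is
        ``1/(1 + sigma)``.
    k_eq_p, k_eq_h : float
        Dimensionless equilibrium constants ``N[MT]/K_d``.  Setting one of
        them to 0 encodes the single-mode limit (the other mode only).
    x : float
        Tau:tubulin-dimer ratio ``[Tau]/(N [MT])``.
    h, p : int
        Lattice dimensions: dimers per protofilament and number of
        protofilaments (13 for the canonical microtubule).
    site_length_nm : float
        Physical site length, used only for unit conversion.
    """

    sigma_p: int = 1
    sigma_h: int = 1
    k_eq_p: float = 1.0
    k_eq_h: float = 1.0
    x: float = 1.0
    h: int = 615
    p: int = 13
    site_length_nm: float = SITE_LENGTH_NM

    def __post_init__(self) -> None:
        if int(self.sigma_p) != self.sigma_p or self.sigma_p < 0:
            raise ValueError(f"sigma_p must be a non-negative integer, got {self.sigma_p}")
        if int(self.sigma_h) != self.sigma_h or self.sigma_h < 0:
            raise ValueError(f"sigma_h must be a non-negative integer, got {self.sigma_h}")
        object.__setattr__(self, "sigma_p", int(self.sigma_p))
        object.__setattr__(self, "sigma_h", int(self.sigma_h))
        if self.k_eq_p < 0 or self.k_eq_h < 0:
            raise ValueError("equilibrium constants must be >= 0")
        if self.k_eq_p == 0 and self.k_eq_h == 0:
            raise ValueError("at least one of k_eq_p, k_eq_h must be positive")
        if not self.x > 0:
            raise ValueError(f"x must be > 0, got {self.x}")
        if self.h < 1 or self.p < 1:
            raise ValueError("lattice dimensions h, p must be >= 1")
        if not self.site_length_nm > 0:
            raise ValueError("site_length_nm must be > 0")

    # ------------------------------------------------------------------ #
    # derived quantities

    @property
    def n_sites(self) -> int:
        """Total number of binding sites N = h * p."""
        return self.h * self.p

    @property
    def k_eff(self) -> float:
        """Effective equilibrium constant k_eq_p + k_eq_h."""
        return self.k_eq_p + self.k_eq_h

    @property
    def kappa(self) -> float:
        """Ratio k_eq_p / k_eq_h = K_d,h / K_d,p (inf/0 in single-mode limits)."""
        if self.k_eq_h == 0:
            return np.inf
        return self.k_eq_p / self.k_eq_h

    @property
    def stoichiometry_matrix(self) -> np.ndarray:
        """2x2 Tau:binding-site stoichiometry matrix.

        Diagonal entries are the mode stoichiometries ``1/(1 + sigma_i)``;
        off-diagonal entries are the apparent projection stoichiometries
        (a bound Tau projects onto a single site of the transverse axis).
        """
        return np.array(
            [
                [1.0 / (1 + self.sigma_p), 1.0],
                [1.0, 1.0 / (1 + self.sigma_h)],
            ]
        )

    def sigma(self, mode: str) -> int:
        """Binding size for ``mode`` in {"p", "h"}."""
        return {"p": self.sigma_p, "h": self.sigma_h}[_norm_mode(mode)]

    def k_eq(self, mode: str) -> float:
        return {"p": self.k_eq_p, "h": self.k_eq_h}[_norm_mode(mode)]

    def saturation_coverage(self, mode: str) -> float:
        """Single-mode saturation coverage 1/(1 + sigma_mode)."""
        return 1.0 / (1 + self.sigma(mode))

    @property
    def active_modes(self) -> tuple[str, ...]:
        modes = []
        if self.k_eq_p > 0:
            modes.append("p")
        if self.k_eq_h > 0:
            modes.append("h")
        return tuple(modes)

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def warn_if_outside_axonal_range(self) -> list[str]:
        """Emit (and return) warnings when x or k_eff leave the axonal ranges."""
        messages = []
        if not _X_RANGE[0] <= self.x <= _X_RANGE[1]:
            messages.append(
                f"x = {self.x:g} is outside the axonal range "
                f"[{_X_RANGE[0]:g}, {_X_RANGE[1]:g}]"
            )
        if not _KEFF_RANGE[0] <= self.k_eff <= _KEFF_RANGE[1]:
            messages.append(
                f"k_eff = {self.k_eff:g} is outside the axonal range "
                f"[{_KEFF_RANGE[0]:g}, {_KEFF_RANGE[1]:g}]"
            )
        for msg in messages:
            warnings.warn(msg, PhysiologicalRangeWarning, stacklevel=2)
        return messages

    def to_dict(self) -> dict:
        return {
            "sigma_p": self.sigma_p,
            "sigma_h": self.sigma_h,
            "k_eq_p": self.k_eq_p,
            "k_eq_h": self.k_eq_h,
            "x": self.x,
            "h": self.h,
            "p": self.p,
            "site_length_nm": self.site_length_nm,
        }


def _norm_mode(mode: str) -> str:
    m = str(mode).lower()
    if m not in ("p", "h"):
        raise ValueError(f"mode must be 'p' or 'h', got {mode!r}")
    return m


@dataclass(frozen=True)
class EquilibriumCoverages:
    """Equilibrium coverages (bound Tau per binding site) of the two modes.

    ``availability`` is the free-site fraction seen by an incoming Tau,
    ``A = 1 - (1+sigma_p) rho_p - (1+sigma_h) rho_h``; the state is
    saturated when A = 0.  The order parameter
    ``S = (1+sigma_p) rho_p - (1+sigma_h) rho_h`` is +1 for a lattice
    saturated with longitudinal Taus and -1 for lateral ones.
    """

    rho_p: float
    rho_h: float
    sigma_p: int
    sigma_h: int
    residual: float = 0.0
    _atol: float = field(default=1e-12, repr=False)

    def __post_init__(self) -> None:
        tol = self._atol
        if self.rho_p < -tol or self.rho_h < -tol:
            raise ValueError(
                f"coverages must be non-negative: rho_p={self.rho_p}, rho_h={self.rho_h}"
            )
        if self.availability < -tol:
            raise ValueError(
                "coverages outside the physical triangle: "
                f"1 - (1+{self.sigma_p})*{self.rho_p} - (1+{self.sigma_h})*{self.rho_h} "
                f"= {self.availability} < 0"
            )

    @classmethod
    def from_rhos(
        cls, rho_p: float, rho_h: float, params: ModelParams, residual: float = 0.0
    ) -> "EquilibriumCoverages":
        return cls(
            rho_p=float(rho_p),
            rho_h=float(rho_h),
            sigma_p=params.sigma_p,
            sigma_h=params.sigma_h,
            residual=float(residual),
        )

    @property
    def rho(self) -> float:
        """Total coverage rho_p + rho_h."""
        return self.rho_p + self.rho_h

    @property
    def availability(self) -> float:
        return 1.0 - (1 + self.sigma_p) * self.rho_p - (1 + self.sigma_h) * self.rho_h

    @property
    def order_parameter(self) -> float:
        return (1 + self.sigma_p) * self.rho_p - (1 + self.sigma_h) * self.rho_h

    @property
    def saturated(self) -> bool:
        return self.availability <= self._atol

    def rho_mode(self, mode: str) -> float:
        return {"p": self.rho_p, "h": self.rho_h}[_norm_mode(mode)]

    def to_dict(self) -> dict:
        return {
            "rho_p": self.rho_p,
            "rho_h": self.rho_h,
            "rho": self.rho,
            "order_parameter": self.order_parameter,
            "availability": self.availability,
            "saturated": self.saturated,
        }
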