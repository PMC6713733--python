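"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from taudecor import ModelParams


@pytest.fixture
def sigma1_params():
    """Canonical sigma_p = sigma_h = 1 two-mode parameter set."""
    return ModelParams(sigma_p=1, sigma_h=1, k_eq_p=2.0, k_eq_h=1.0, x=1.0)


def exact_canonical_coverages(
    params: ModelParams, grand_canonical: bool = False
) -> tuple[float, float]:
    """Exact equilibrium coverages by exhaustive configuration enumeration.

    Independent of both the mean-field solver and the Monte Carlo kernel:
    enumerates every admissible arrangement of p- and h-molecules on the
    (tiny) lattice and weights it by the detailed-balance stationary
    measure of a chain with per-anchor attach rate k_i * c_free and
    per-molecule detach rate 1,

        canonical:        pi(C) ∝ k_p^n_p k_h^n_h M! / ((M - n)! N^n)
        grand canonical:  pi(C) ∝ (k_p x)^n_p (k_h x)^n_h.

    Cost is exponential in the lattice size — use only for a handful of
    sites.
    """
    h, p, sp, sh = params.h, params.p, params.sigma_p, params.sigma_h
    N = h * p
    M = int(round(params.x * N))
    kp, kh = params.k_eq_p, params.k_eq_h
    acc = {"Z": 0.0, "np": 0.0, "nh": 0.0}

    def weight(n_p, n_h):
        if grand_canonical:
            return (kp * params.x) ** n_p * (kh * params.x) ** n_h
        n = n_p + n_h
        if n > M:
            return 0.0
        w = kp**n_p * kh**n_h / N**n
        for t in range(n):
            w *= M - t
        return w

    grid = [0] * N

    def rec(site, n_p, n_h):
        if site == N:
            w = weight(n_p, n_h)
            acc["Z"] += w
            acc["np"] += w * n_p
            acc["nh"] += w * n_h
            return
        i, j = divmod(site, p)
        rec(site + 1, n_p, n_h)
        if i + sp < h and all(grid[(i + t) * p + j] == 0 for t in range(sp + 1)):
            for t in range(sp + 1):
                grid[(i + t) * p + j] = 1
            rec(site + 1, n_p + 1, n_h)
            for t in range(sp + 1):
                grid[(i + t) * p + j] = 0
        if j + sh < p and all(grid[i * p + j + t] == 0 for t in range(sh + 1)):
            for t in range(sh + 1):
                grid[i * p + j + t] = 1
            rec(site + 1, n_p, n_h + 1)
            for t in range(sh + 1):
                grid[i * p + j + t] = 0

    rec(0, 0, 0)
    return acc["np"] / acc["Z"] / N, acc["nh"] / acc["Z"] / N


def brute_force_spacing_census(state, direction="parallel"):
    """Nearest-neighbor center distances read directly off a lattice state.

    Re-derives the census from the molecule table (mode, anchor, size)
    without the compiled kernel: a p-molecule has center i + sigma_p/2 on
    its protofilament column, an h-molecule center j + sigma_h/2 on its
    helix row, and each molecule projects onto a single site of every
    transverse line it crosses.  Returns a list of distances in site units.
    """
    params = state.params
    sp, sh = params.sigma_p, params.sigma_h
    lines: dict[int, list[float]] = {}
    for mode, (i, j), sigma in state.molecules.values():
        if direction == "parallel":
            if mode == "p":
                lines.setdefault(j, []).append(i + sp / 2.0)
            else:
                for t in range(sigma + 1):
                    lines.setdefault(j + t, []).append(float(i))
        else:
            if mode == "h":
                lines.setdefault(i, []).append(j + sh / 2.0)
            else:
                for t in range(sigma + 1):
                    lines.setdefault(i + t, []).append(float(j))
    out = []
    for centers in lines.values():
        centers.sort()
        out.extend(b - a for a, b in zip(centers, centers[1:]))
    return out
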