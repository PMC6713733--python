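"""Kinetic Monte Carlo simulation of Tau decoration on the microtubule lattice.

The lattice is ``h x p`` tubulin dimers (rows run along a protofilament,
columns index the 13 protofilaments).  Tau molecules attach reversibly in
two modes under strict exclusion: a p-mode molecule covers ``1 + sigma_p``
consecutive sites of one protofilament, an h-mode molecule ``1 + sigma_h``
adjacent protofilaments on one helix row; no partial, overlapping or
stacked binding, open ends along the protofilament axis, and no lateral
binding across the seam.

The dynamics is a Gillespie chain with a finite Tau reservoir of
``round(x * N)`` molecules (canonical ensemble, honoring x as a closed-
system ratio; a grand-canonical variant holding the free concentration
fixed at x is available).  Only rate ratios matter at equilibrium, so the
off-rates are fixed to 1 and the per-anchor on-rates to ``k_eq_i * c_free``.
Its stationary state obeys detailed balance with the mean-field isotherms
of :mod:`taudecor.model_core`, which is what the sampled coverages and
nearest-neighbor histograms are validated against.

Two implementations share the event rules: a transparent pure-Python
:class:`LatticeState` / :func:`gillespie_step` pair used for snapshots and
invariant checking, and the compiled kernel behind :func:`run` used for
production sampling on the 615 x 13 lattice.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .params import ModelParams, _norm_mode

__all__ = [
    "LatticeState",
    "SimulationSummary",
    "enumerate_placements",
    "gillespie_step",
    "run",
    "snapshot",
    "load_snapshot",
]

_MODE_CODE = {"p": 0, "h": 1}
_MODE_NAME = {0: "p", 1: "h"}


# --------------------------------------------------------------------- #
# lattice state (reference implementation)


class LatticeState:
    """Occupancy state of the h x p lattice with a finite Tau reservoir."""

    def __init__(self, params: ModelParams, n_tau_total: int | None = None):
        self.params = params
        self.h = params.h
        self.p = params.p
        #: molecule id per site, -1 = empty
        self.grid = np.full((self.h, self.p), -1, dtype=np.int64)
        #: id -> (mode, (i, j), size)
        self.molecules: dict[int, tuple[str, tuple[int, int], int]] = {}
        if n_tau_total is None:
            n_tau_total = int(round(params.x * params.n_sites))
        self.n_tau_total = int(n_tau_total)
        self._next_id = 0
        self.time = 0.0

    # -- bookkeeping ----------------------------------------------------

    @property
    def n_bound(self) -> int:
        return len(self.molecules)

    @property
    def n_free_tau(self) -> int:
        return self.n_tau_total - self.n_bound

    def n_bound_mode(self, mode: str) -> int:
        mode = _norm_mode(mode)
        return sum(1 for m, _, _ in self.molecules.values() if m == mode)

    def coverage(self, mode: str) -> float:
        return self.n_bound_mode(mode) / self.params.n_sites

    def footprint(self, mode: str, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Row and column indices covered by a molecule anchored at (i, j)."""
        sigma = self.params.sigma(mode)
        if mode == "p":
            return np.arange(i, i + sigma + 1), np.full(sigma + 1, j)
        return np.full(sigma + 1, i), np.arange(j, j + sigma + 1)

    def is_valid_anchor(self, mode: str, i: int, j: int) -> bool:
        """Exclusion, open-boundary and seam rules for an anchor site."""
        mode = _norm_mode(mode)
        sigma = self.params.sigma(mode)
        if not (0 <= i < self.h and 0 <= j < self.p):
            return False
        if mode == "p" and i + sigma >= self.h:
            return False
        if mode == "h" and j + sigma >= self.p:  # no wrap across the seam
            return False
        rows, cols = self.footprint(mode, i, j)
        return bool(np.all(self.grid[rows, cols] < 0))

    def attach(self, mode: str, i: int, j: int) -> int:
        mode = _norm_mode(mode)
        if self.n_free_tau <= 0:
            raise ValueError("no free Tau left in the reservoir")
        if not self.is_valid_anchor(mode, i, j):
            raise ValueError(f"invalid anchor ({i}, {j}) for mode {mode!r}")
        mol_id = self._next_id
        self._next_id += 1
        rows, cols = self.footprint(mode, i, j)
        self.grid[rows, cols] = mol_id
        self.molecules[mol_id] = (mode, (i, j), self.params.sigma(mode))
        return mol_id

    def detach(self, mol_id: int) -> None:
        mode, (i, j), _ = self.molecules.pop(mol_id)
        rows, cols = self.footprint(mode, i, j)
        self.grid[rows, cols] = -1

    def check_invariants(self) -> None:
        """Raise AssertionError on any broken exclusion/conservation rule."""
        seen = np.zeros_like(self.grid, dtype=bool)
        for mol_id, (mode, (i, j), sigma) in self.molecules.items():
            assert sigma == self.params.sigma(mode)
            if mode == "p":
                assert i + sigma < self.h, "p-molecule exceeds the protofilament"
            else:
                assert j + sigma < self.p, "h-molecule crosses the seam"
            rows, cols = self.footprint(mode, i, j)
            assert not seen[rows, cols].any(), "overlapping molecules"
            seen[rows, cols] = True
            assert np.all(self.grid[rows, cols] == mol_id), "grid/molecule mismatch"
        assert int(seen.sum()) == sum(
            1 + s for _, _, s in self.molecules.values()
        ), "site count mismatch"
        assert np.all((self.grid >= 0) == seen), "stray occupied sites"
        assert self.n_free_tau >= 0, "reservoir overdrawn"
        assert self.n_free_tau + self.n_bound == self.n_tau_total, "Tau not conserved"


def enumerate_placements(state: LatticeState, mode: str):
    """Count admissible anchors for ``mode`` and return a uniform sampler.

    Returns ``(count, sampler)`` where ``sampler(rng)`` draws a uniformly
    random admissible anchor (i, j).
    """
    mode = _norm_mode(mode)
    sigma = state.params.sigma(mode)
    empty = state.grid < 0
    if mode == "p":
        if state.h - sigma <= 0:
            valid = np.zeros((0, state.p), dtype=bool)
        else:
            valid = np.logical_and.reduce(
                [empty[t : state.h - sigma + t, :] for t in range(sigma + 1)]
            )
    else:
        if state.p - sigma <= 0:
            valid = np.zeros((state.h, 0), dtype=bool)
        else:
            valid = np.logical_and.reduce(
                [empty[:, t : state.p - sigma + t] for t in range(sigma + 1)]
            )
    anchors = np.argwhere(valid)
    count = len(anchors)

    def sampler(rng: np.random.Generator) -> tuple[int, int]:
        if count == 0:
            raise ValueError(f"no admissible anchor for mode {mode!r}")
        i, j = anchors[rng.integers(count)]
        return int(i), int(j)

    return count, sampler


def gillespie_step(
    state: LatticeState,
    params: ModelParams,
    rng: np.random.Generator,
    grand_canonical: bool = False,
) -> str:
    """Execute one Gillespie event in place; returns the event label.

    Propensities: attach in mode i at rate ``k_eq_i * c_free * M_i`` with
    M_i admissible anchors, detach at rate 1 per bound molecule.  Raises
    RuntimeError in the absorbing zero-Tau state.
    """
    N = params.n_sites
    c_free = params.x if grand_canonical else state.n_free_tau / N
    counts = {}
    samplers = {}
    rates = []
    labels = []
    for mode in ("p", "h"):
        counts[mode], samplers[mode] = enumerate_placements(state, mode)
        rates.append(params.k_eq(mode) * c_free * counts[mode])
        labels.append(f"attach_{mode}")
    for mode in ("p", "h"):
        rates.append(float(state.n_bound_mode(mode)))
        labels.append(f"detach_{mode}")
    rates = np.array(rates)
    total = rates.sum()
    if total <= 0:
        raise RuntimeError("absorbing state: all propensities are zero (no Tau)")
    state.time += rng.exponential(1.0 / total)
    event = labels[int(rng.choice(4, p=rates / total))]
    kind, mode = event.split("_")
    if kind == "attach":
        i, j = samplers[mode](rng)
        state.attach(mode, i, j)
    else:
        ids = [k for k, (m, _, _) in state.molecules.items() if m == mode]
        state.detach(ids[int(rng.integers(len(ids)))])
    return event


# --------------------------------------------------------------------- #
# snapshots


def snapshot(state: LatticeState) -> str:
    """Lossless TSV export of the occupancy grid.

    One row per occupied site with molecule id, mode and anchor, preceded
    by a header of ``#key=value`` lines; round-trips via
    :func:`load_snapshot`.
    """
    buf = io.StringIO()
    buf.write(f"#h={state.h}\n#p={state.p}\n")
    buf.write(f"#sigma_p={state.params.sigma_p}\n#sigma_h={state.params.sigma_h}\n")
    buf.write(f"#n_tau_total={state.n_tau_total}\n")
    buf.write("molecule_id\tmode\tanchor_i\tanchor_j\tsize\n")
    for mol_id in sorted(state.molecules):
        mode, (i, j), sigma = state.molecules[mol_id]
        buf.write(f"{mol_id}\t{mode}\t{i}\t{j}\t{sigma}\n")
    return buf.getvalue()


def load_snapshot(text: str, params: ModelParams | None = None) -> LatticeState:
    """Rebuild a :class:`LatticeState` from its TSV snapshot."""
    header = {}
    lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            header[key] = int(val)
        elif line.strip():
            lines.append(line)
    if params is None:
        params = ModelParams(
            sigma_p=header["sigma_p"],
            sigma_h=header["sigma_h"],
            x=max(header["n_tau_total"], 1) / (header["h"] * header["p"]),
            h=header["h"],
            p=header["p"],
        )
    state = LatticeState(params, n_tau_total=header["n_tau_total"])
    for line in lines[1:]:  # skip the column header
        mol_id, mode, i, j, _sigma = line.split("\t")
        state.attach(mode, int(i), int(j))
        # keep the original ids so the export round-trips
        new_id = state._next_id - 1
        if new_id != int(mol_id):
            state.molecules[int(mol_id)] = state.molecules.pop(new_id)
            rows, cols = state.footprint(mode, int(i), int(j))
            state.grid[rows, cols] = int(mol_id)
            state._next_id = max(state._next_id, int(mol_id) + 1)
    return state


# --------------------------------------------------------------------- #
# production runs


@dataclass
class SimulationSummary:
    """Monte Carlo estimates of coverages and spacing histograms.

    Coverage standard errors come from batch means (20 batches of the
    sampled configurations), which absorbs the residual autocorrelation
    between samples.  Histograms are nearest-neighbor center-to-center
    distance counts in half-site bins (``r = bin/2`` sites).
    """

    params: ModelParams
    seed: int
    n_samples: int
    sample_interval: float
    burnin_time: float
    rho_p: float
    rho_h: float
    rho_p_se: float
    rho_h_se: float
    rho: float = field(init=False)
    rho_se: float = field(init=False)
    hist_parallel: np.ndarray | None = None
    hist_perp: np.ndarray | None = None
    hist_parallel_batches: np.ndarray | None = None
    hist_perp_batches: np.ndarray | None = None
    pair_hist_parallel: np.ndarray | None = None
    pair_hist_perp: np.ndarray | None = None
    burnin_trace: pd.DataFrame | None = None
    burnin_warning: str | None = None
    simulated_time: float = 0.0
    final_state: LatticeState | None = None

    def __post_init__(self):
        self.rho = self.rho_p + self.rho_h
        # joint SE; mode counts are anticorrelated at most, the sum bound holds
        self.rho_se = float(np.hypot(self.rho_p_se, self.rho_h_se))

    def spacing_pmf(self, direction: str = "parallel"):
        """Normalized spacing pmf and its per-bin batch-means SE.

        Returns ``(r_sites, pmf, se)`` over the recorded half-site grid.
        """
        batches = (
            self.hist_parallel_batches
            if direction == "parallel"
            else self.hist_perp_batches
        )
        if batches is None:
            raise ValueError("histograms were not collected in this run")
        totals = batches.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        pmfs = batches / totals
        nb = pmfs.shape[0]
        pmf = pmfs.mean(axis=0)
        se = pmfs.std(axis=0, ddof=1) / np.sqrt(nb)
        r = 0.5 * np.arange(pmfs.shape[1])
        return r, pmf, se

    def provenance(self) -> dict:
        return {
            "package": "taudecor",
            "version": __version__,
            "params": self.params.to_dict(),
            "seed": int(self.seed),
            "n_samples": int(self.n_samples),
            "sample_interval": float(self.sample_interval),
            "burnin_time": float(self.burnin_time),
        }

    def to_dict(self) -> dict:
        out = {
            "rho_p": self.rho_p,
            "rho_h": self.rho_h,
            "rho": self.rho,
            "rho_p_se": self.rho_p_se,
            "rho_h_se": self.rho_h_se,
            "rho_se": self.rho_se,
            "simulated_time": self.simulated_time,
            "burnin_warning": self.burnin_warning,
            "provenance": self.provenance(),
        }
        return out

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)


def _batch_se(samples: np.ndarray, n_batches: int = 20) -> float:
    n = len(samples)
    nb = min(n_batches, n)
    if nb < 2:
        return float("nan")
    usable = (n // nb) * nb
    means = samples[:usable].reshape(nb, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(nb))


def run(
    params: ModelParams,
    n_samples: int = 10_000,
    sample_interval: float = 1.0,
    burnin_time: float = 50.0,
    seed: int = 0,
    collect_histograms: bool = True,
    r_max_sites: float = 30.0,
    n_batches: int = 20,
    grand_canonical: bool = False,
    keep_final_state: bool = True,
) -> SimulationSummary:
    """Run the compiled Gillespie chain and summarize its stationary samples.

    Time is measured in mean bound-Tau lifetimes (1/k_off).  After a
    burn-in of ``burnin_time``, ``n_samples`` configurations are recorded
    on a uniform time grid spaced ``sample_interval`` apart — one
    lifetime between samples, so successive configurations are close to
    decorrelated (the residual correlation is absorbed by the
    batch-means errors).  Reproducible for a given ``seed``.
    """
    from ._kernels import run_kmc

    N = params.n_sites
    n_tau_total = int(round(params.x * N))
    rmax_half = int(round(2 * r_max_sites))
    n_trace = 200

    (
        samp_p,
        samp_h,
        hist_par,
        hist_perp,
        pair_par,
        pair_perp,
        trace_p,
        trace_h,
        occ_mode,
        anc_i,
        anc_j,
        t_sim,
    ) = run_kmc(
        params.h,
        params.p,
        params.sigma_p,
        params.sigma_h,
        float(params.k_eq_p),
        float(params.k_eq_h),
        n_tau_total,
        bool(grand_canonical),
        float(params.x),
        float(burnin_time),
        int(n_samples),
        float(sample_interval),
        int(np.uint32(seed)),
        rmax_half,
        bool(collect_histograms),
        int(n_batches),
        n_trace,
    )

    rho_p_samp = samp_p / N
    rho_h_samp = samp_h / N
    warning = None
    if n_samples < 10 * n_batches:
        warning = (
            f"only {n_samples} samples for {n_batches} batches; "
            "standard errors are unreliable"
        )
    # Geweke-style drift check on the burn-in trace of the total coverage
    trace = (trace_p + trace_h) / N
    first, last = trace[: len(trace) // 5], trace[-len(trace) // 2 :]
    spread = trace.std() + 1e-12
    if abs(first.mean() - last.mean()) > 4.0 * spread / np.sqrt(len(first)):
        drift = abs(first.mean() - last.mean())
        warning = (warning + "; " if warning else "") + (
            f"burn-in trace still drifting (|Δrho| = {drift:.3g}); "
            "consider a longer burnin_time"
        )

    summary = SimulationSummary(
        params=params,
        seed=seed,
        n_samples=n_samples,
        sample_interval=sample_interval,
        burnin_time=burnin_time,
        rho_p=float(rho_p_samp.mean()),
        rho_h=float(rho_h_samp.mean()),
        rho_p_se=_batch_se(rho_p_samp, n_batches),
        rho_h_se=_batch_se(rho_h_samp, n_batches),
        hist_parallel=hist_par.sum(axis=0) if collect_histograms else None,
        hist_perp=hist_perp.sum(axis=0) if collect_histograms else None,
        hist_parallel_batches=hist_par if collect_histograms else None,
        hist_perp_batches=hist_perp if collect_histograms else None,
        pair_hist_parallel=pair_par if collect_histograms else None,
        pair_hist_perp=pair_perp if collect_histograms else None,
        burnin_trace=pd.DataFrame(
            {"rho_p": trace_p / N, "rho_h": trace_h / N}
        ),
        burnin_warning=warning,
        simulated_time=float(t_sim),
    )
    if keep_final_state:
        summary.final_state = _state_from_grids(params, n_tau_total, occ_mode, anc_i, anc_j)
    return summary


def _state_from_grids(params, n_tau_total, occ_mode, anc_i, anc_j) -> LatticeState:
    state = LatticeState(params, n_tau_total=n_tau_total)
    anchors = set()
    h, p = occ_mode.shape
    for i in range(h):
        for j in range(p):
            if occ_mode[i, j] >= 0:
                anchors.add((_MODE_NAME[int(occ_mode[i, j])], int(anc_i[i, j]), int(anc_j[i, j])))
    for mode, i, j in sorted(anchors):
        state.attach(mode, i, j)
    return state
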