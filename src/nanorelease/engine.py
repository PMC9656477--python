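"""Brownian-dynamics propagation with hard-sphere rejection.

Solutes follow the Cichocki-Hinsen scheme: each step proposes a free
Brownian displacement with per-component standard deviation
sqrt(2 D0 dt); the move is rejected if it would overlap another particle.
In flexible mode the network beads additionally feel Hookean bond forces
through the overdamped drift term D0 F dt / kBT (kBT = 1 in reduced
units).  Bonded pairs are exempt from the hard-sphere check - the bond
rest length equals the contact distance, so the harmonic potential alone
governs bonded separations.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels as K
from .model import BeadSystem, NetworkTopology, RNGStream, SimulationParams, SOLUTE

_EMPTY_BONDS = np.empty((0, 2), dtype=np.int64)


def free_displacement(D0: float, dt: float, rng: RNGStream) -> np.ndarray:
    """Free Brownian trial displacement (nm): sqrt(2 D0 dt) N(0,1) per axis."""
    if D0 < 0 or dt <= 0:
        raise ValueError("D0 must be >= 0 and dt > 0")
    return math.sqrt(2.0 * D0 * dt) * rng.standard_normal(3)


def forced_displacement(
    D0: float, F: np.ndarray, dt: float, rng: RNGStream
) -> np.ndarray:
    """Brownian displacement with drift: free part + D0 F dt (kBT = 1)."""
    F = np.asarray(F, dtype=np.float64)
    return free_displacement(D0, dt, rng) + D0 * F * dt


def bond_forces(system: BeadSystem, topology: NetworkTopology) -> np.ndarray:
    """Per-bead Hookean bond forces (kBT/nm), Newton's third law pairwise.

    Force on j from i is -ke (rij - r0) along the unit vector from i to j.
    """
    pos = system.positions
    i, j = topology.bonds[:, 0], topology.bonds[:, 1]
    d = pos[j] - pos[i]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-10):
        raise ValueError("coincident bonded beads: bond force direction undefined")
    fij = (-topology.ke * (r - topology.r0) / r)[:, None] * d
    forces = np.zeros_like(pos)
    np.add.at(forces, j, fij)
    np.add.at(forces, i, -fij)
    return forces


class BrownianEngine:
    """Stateful propagator for one system + topology + parameter set.

    Keeps the cell grid and force buffers alive across calls so that long
    runs can be advanced in chunks (for sampling) without rebuild cost.
    The internal random stream is seeded once from ``params.seed`` (or an
    explicit ``seed``); identical seeds give identical trajectories.
    """

    def __init__(
        self,
        system: BeadSystem,
        topology: NetworkTopology | None,
        params: SimulationParams,
        seed: int | None = None,
        total_time_ns: float | None = None,
    ):
        self.system = system.copy()
        self.topology = topology
        self.params = params
        self.flexible = params.mode == "flexible"
        n = self.system.n_beads

        bonds = topology.bonds if topology is not None else _EMPTY_BONDS
        self._bonds = np.ascontiguousarray(bonds, dtype=np.int64)
        ke = topology.ke if topology is not None else 0.0
        r0 = topology.r0 if topology is not None else 1.0
        self._ke, self._r0 = float(ke), float(r0)
        if topology is not None:
            ptr, idx = topology.partners_csr(n)
        else:
            ptr, idx = np.zeros(n + 1, dtype=np.int64), np.empty(0, dtype=np.int64)
        self._pptr, self._pidx = ptr, idx
        # the hard-sphere check applies to every pair, bonded or not: the
        # rejection rule is unqualified, so bonds fluctuate only outward of
        # contact (their length statistics follow the r >= r0 restricted
        # Boltzmann distribution)
        self._xptr = np.zeros(n + 1, dtype=np.int64)
        self._xidx = np.empty(0, dtype=np.int64)

        if self.flexible:
            mobile = np.arange(n, dtype=np.int64)
        else:
            mobile = np.nonzero(self.system.kinds == SOLUTE)[0].astype(np.int64)
        self.mobile = mobile
        self._perm = np.empty_like(mobile)
        self._forces = np.zeros((n, 3), dtype=np.float64)
        dt = params.dt_ns
        self._dt = dt
        self._sqrtcoef = np.sqrt(2.0 * self.system.D0 * dt)
        immobile = np.ones(n, dtype=bool)
        immobile[mobile] = False
        self._sqrtcoef[immobile] = 0.0

        if total_time_ns is None:
            total_time_ns = params.n_steps * dt
        self._build_grid(total_time_ns)
        self.seed = int(params.seed if seed is None else seed) % 2**31
        K.seed_rng(self.seed)  # permutation stream (numba)
        self._np_gen = np.random.Generator(np.random.PCG64(self.seed))
        self.accepted = 0
        self.attempted = 0
        self.overlap_violations = 0
        self.steps_done = 0

    # -- grid management -------------------------------------------------
    def _build_grid(self, total_time_ns: float, scale: float = 1.0):
        sys_ = self.system
        net = sys_.network_mask
        diam = 2.0 * sys_.radii
        # cell edge: the largest diameter of the majority species keeps
        # occupancy low; the per-bead scan radius restores correctness for
        # larger contact distances.
        edge = float(diam[net].max() if net.any() else diam.max())
        extent = float(np.abs(sys_.positions).max()) if sys_.n_beads else 1.0
        d0max = float(sys_.D0[self.mobile].max()) if len(self.mobile) else 0.0
        # keep the grid tight (cache-resident head array); a bead reaching
        # the rim triggers a rebuild at 1.5x, so the allowance only trades
        # rebuild frequency against memory traffic
        allow = min(
            5.0 * math.sqrt(6.0 * d0max * max(total_time_ns, 0.0) + 1e-12),
            0.3 * extent + 4.0 * edge,
        )
        half = (extent + allow + 3.0 * edge) * scale
        half = min(half, self.params.box_side / 2.0 + 2.0 * edge)
        nc = int(math.ceil(2.0 * half / edge)) + 2
        if nc > 200:  # cap memory; scan radii compensate for a larger edge
            nc = 200
            edge = 2.0 * half / (nc - 2)
        self._edge = edge
        self._nc = nc
        self._gmin = -edge * nc / 2.0
        rmax = float(sys_.radii.max())
        self._scanr = np.ceil((sys_.radii + rmax) / edge - 1e-12).astype(np.int64)
        d = np.array([-1, 0, 1])
        self._offs27 = np.array(
            [(dx * nc + dy) * nc + dz for dx in d for dy in d for dz in d],
            dtype=np.int64,
        )
        self._head = np.full(nc**3, -1, dtype=np.int32)
        self._nxt = np.empty(sys_.n_beads, dtype=np.int32)
        self._prv = np.empty(sys_.n_beads, dtype=np.int32)
        self._cellof = np.empty(sys_.n_beads, dtype=np.int32)
        K.build_cells(
            sys_.positions, self._gmin, edge, nc,
            self._head, self._nxt, self._prv, self._cellof,
        )

    # -- propagation -----------------------------------------------------
    def advance(self, n_steps: int, check_every: int = 0, check_tol: float = 1e-9):
        """Run ``n_steps`` steps in place; returns self for chaining."""
        remaining = int(n_steps)
        nm = max(len(self.mobile), 1)
        max_chunk = max(1, min(512, 8_000_000 // nm))
        while remaining > 0:
            chunk = min(remaining, max_chunk)
            normals = self._np_gen.standard_normal((chunk, len(self.mobile), 3))
            acc, att, viol, done, status = K.run_steps(
                self.system.positions,
                self.system.radii,
                self.system.D0,
                self.mobile,
                self._scanr,
                self._sqrtcoef,
                self._bonds,
                self._ke,
                self._r0,
                self.flexible,
                self._xptr,
                self._xidx,
                self._pptr,
                self._pidx,
                self._dt,
                chunk,
                self._gmin,
                self._edge,
                self._nc,
                self._head,
                self._nxt,
                self._prv,
                self._cellof,
                self.params.box_side / 2.0,
                self._forces,
                self._perm,
                self._offs27,
                normals,
                int(check_every),
                float(check_tol),
            )
            self.accepted += acc
            self.attempted += att
            self.overlap_violations += viol
            self.steps_done += done
            if status == K.COINCIDENT_BOND:
                raise RuntimeError("coincident bonded beads during propagation")
            if status == K.GRID_OVERFLOW:
                # a bead reached the edge of the cell grid: enlarge and resume
                self._build_grid(
                    (remaining - done) * self._dt, scale=1.5
                )
                remaining -= done
                continue
            remaining -= done
        return self

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.attempted if self.attempted else float("nan")

    def snapshot(self) -> BeadSystem:
        return self.system.copy()


def detect_overlap(
    system: BeadSystem,
    index: int,
    trial_position,
    exempt=(),
) -> bool:
    """Would bead ``index`` at ``trial_position`` overlap any bead not in
    ``exempt``?  Cell-list backed; equivalent to the O(N) all-pairs check."""
    trial = np.asarray(trial_position, dtype=np.float64)
    pos = system.positions
    edge = float(2.0 * system.radii.max())
    lo = min(float(pos.min()), float(trial.min())) - 2 * edge
    hi = max(float(pos.max()), float(trial.max())) + 2 * edge
    nc = min(int(math.ceil((hi - lo) / edge)) + 1, 256)
    edge = max(edge, (hi - lo) / nc)
    n = system.n_beads
    head = np.full(nc**3, -1, dtype=np.int32)
    nxt = np.empty(n, dtype=np.int32)
    prv = np.empty(n, dtype=np.int32)
    cellof = np.empty(n, dtype=np.int32)
    K.build_cells(pos, lo, edge, nc, head, nxt, prv, cellof)
    ex = np.asarray(sorted(set(int(e) for e in exempt)), dtype=np.int64)
    pptr = np.zeros(n + 1, dtype=np.int64)
    pptr[index + 1 :] = len(ex)
    scanr = int(math.ceil((system.radii[index] + system.radii.max()) / edge))
    return bool(
        K.trial_overlaps(
            index, trial[0], trial[1], trial[2], pos, system.radii,
            scanr, lo, edge, nc, head, nxt, pptr, ex,
        )
    )


def step(
    system: BeadSystem,
    topology: NetworkTopology | None,
    params: SimulationParams,
    rng: RNGStream,
) -> BeadSystem:
    """Advance one Brownian-dynamics step and return the new configuration.

    Functional single-step interface; long runs should use
    :class:`BrownianEngine` directly, which keeps its cell grid between
    steps.  The kernel stream is seeded from a draw of ``rng`` so repeated
    calls follow the parent stream deterministically.
    """
    sub_seed = int(rng.integers(0, 2**31))
    eng = BrownianEngine(system, topology, params, seed=sub_seed,
                         total_time_ns=params.dt_ns)
    eng.advance(1)
    return eng.snapshot()


def estimate_diffusion(
    trajectory: np.ndarray,
    times: np.ndarray,
    t_window: tuple[float, float] | None = None,
    full: bool = False,
):
    """Diffusion coefficient from the MSD slope: D = slope / 6.

    ``trajectory`` is (T, 3) for one walker or (T, M, 3) for an ensemble;
    ``times`` the matching sample times (ns).  The MSD relative to the
    first frame is fitted linearly (least squares, zero intercept not
    enforced) over ``t_window``; with ``full=True`` returns (D, R2) so a
    non-diffusive (e.g. ballistic) input can be flagged by its poor R2.
    """
    traj = np.asarray(trajectory, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if traj.ndim == 2:
        traj = traj[:, None, :]
    if traj.shape[0] != len(times) or len(times) < 2:
        raise ValueError("need at least 2 time points matching the trajectory")
    disp = traj - traj[0]
    msd = np.mean(np.sum(disp**2, axis=2), axis=1)
    if t_window is not None:
        sel = (times >= t_window[0]) & (times <= t_window[1])
        if sel.sum() < 2:
            raise ValueError("t_window selects fewer than 2 samples")
    else:
        sel = slice(None)
    t_fit, m_fit = times[sel], msd[sel]
    slope, intercept = np.polyfit(t_fit, m_fit, 1)
    model = slope * t_fit + intercept
    ss_tot = np.sum((m_fit - m_fit.mean()) ** 2)
    r2 = 1.0 - np.sum((m_fit - model) ** 2) / ss_tot if ss_tot > 0 else 1.0
    d = slope / 6.0
    return (float(d), float(r2)) if full else float(d)
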