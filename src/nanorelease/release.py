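"""Drug loading, release-experiment orchestration and replicate averaging.

A release experiment loads ``n_drug`` solute spheres into the voids of the
nanogel (uniformly in the sphere of radius R_max about the network centre
of mass: R_max = Rng for throughout-loading, R_max = Rcore for
core-loading), then propagates the whole system and counts first exits: a
solute is released the first time its distance from the instantaneous
network centre of mass exceeds the fixed pre-release Rng, and stays
counted even if it later re-enters.  Released solutes keep diffusing and
interacting; no perfect-sink removal is applied.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels as K
from .engine import BrownianEngine
from .kinetics import stokes_einstein
from .model import (
    SOLUTE,
    BeadSystem,
    LoadingSpec,
    NetworkTopology,
    ReleaseCurve,
    RNGStream,
    SimulationParams,
)


def default_sample_times(
    t_end: float, t_start: float = 1e-3, per_decade: int = 64
) -> np.ndarray:
    """Logarithmic sampling schedule (ns), ``per_decade`` points per decade."""
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    n = int(math.ceil(math.log10(t_end / t_start) * per_decade)) + 1
    return np.geomspace(t_start, t_end, n)


def load_solutes(
    system: BeadSystem,
    spec: LoadingSpec,
    rng: RNGStream,
    T: float = 293.0,
    eta: float = 1.002e-3,
) -> BeadSystem:
    """Place ``spec.n_drug`` solutes by rejection sampling; returns a new system.

    Centres are uniform in the sphere of radius ``spec.R_max`` about the
    network centre of mass, accepted iff overlap-free against network
    beads and previously placed solutes.  Raises RuntimeError once any
    solute exhausts ``spec.max_attempts`` (jammed loading).
    """
    rs = spec.solute_diameter / 2.0
    n_old = system.n_beads
    n_new = n_old + spec.n_drug
    pos = np.vstack([system.positions, np.zeros((spec.n_drug, 3))])
    radii = np.concatenate([system.radii, np.full(spec.n_drug, rs)])
    kinds = np.concatenate(
        [system.kinds, np.full(spec.n_drug, SOLUTE, dtype=np.int64)]
    )
    d0 = np.concatenate(
        [system.D0, np.full(spec.n_drug, stokes_einstein(rs, T, eta))]
    )
    com = (
        system.network_com()
        if system.network_mask.any()
        else np.zeros(3)
    )

    edge = float(max(2.0 * radii.max(), 1e-6))
    half = float(np.abs(pos[:n_old]).max() if n_old else 0.0)
    half = max(half, spec.R_max + rs) + 2.0 * edge
    nc = int(math.ceil(2.0 * half / edge)) + 2
    if nc > 200:  # cap memory; the scan radius compensates
        nc = 200
        edge = 2.0 * half / (nc - 2)
    gmin = -edge * nc / 2.0
    head = np.full(nc**3, -1, dtype=np.int32)
    nxt = np.empty(n_new, dtype=np.int32)
    prv = np.empty(n_new, dtype=np.int32)
    cellof = np.empty(n_new, dtype=np.int32)
    # only existing beads enter the grid; solutes are linked as accepted
    K.build_cells(pos[:n_old], gmin, edge, nc, head, nxt, prv, cellof)
    pptr = np.zeros(n_new + 1, dtype=np.int64)
    pidx = np.empty(0, dtype=np.int64)
    scanr_s = max(int(math.ceil((rs + radii.max()) / edge)), 1)
    K.seed_rng(int(rng.integers(0, 2**31)))
    placed = K.place_solutes(
        pos, radii, n_old, spec.n_drug, com.astype(np.float64),
        float(spec.R_max), int(spec.max_attempts), scanr_s,
        gmin, edge, nc, head, nxt, prv, cellof, pptr, pidx,
    )
    if placed < spec.n_drug:
        raise RuntimeError(
            f"jammed loading: solute {placed + 1}/{spec.n_drug} found no "
            f"void in {spec.max_attempts} attempts (diameter "
            f"{spec.solute_diameter} nm, R_max {spec.R_max} nm)"
        )
    return BeadSystem(pos, radii, kinds, d0)


def run_release(
    system: BeadSystem,
    topology: NetworkTopology | None,
    params: SimulationParams,
    Rng: float,
    loading: str = "throughout",
    first_exit: bool = True,
    replicate_id: str | int = 0,
) -> ReleaseCurve:
    """Propagate a loaded system and record the fraction released f(t).

    ``Rng`` is the fixed pre-release geometric radius; the exit test uses
    the instantaneous network centre of mass (which drifts for a flexible
    gel).  ``first_exit=False`` records instead the instantaneous fraction
    outside Rng (sensitivity alternative; the resulting curve is not
    guaranteed monotone and is returned without the monotonicity check).
    """
    solute = np.nonzero(system.kinds == SOLUTE)[0]
    n_drug = len(solute)
    if n_drug == 0:
        raise ValueError("no solutes loaded")
    if Rng <= 0:
        raise ValueError("Rng must be positive")
    dt = params.dt_ns
    if params.sample_times is not None:
        times = params.sample_times
    else:
        if params.n_steps < 1:
            raise ValueError("params.n_steps must be set (or give sample_times)")
        times = default_sample_times(params.n_steps * dt)
    steps = np.unique(np.maximum(np.round(times / dt).astype(np.int64), 1))
    t_grid = steps * dt

    eng = BrownianEngine(
        system, topology, params, total_time_ns=float(t_grid[-1])
    )
    released = np.zeros(n_drug, dtype=bool)
    f = np.empty(len(steps))
    done = 0
    has_network = bool(system.network_mask.any())
    for k, s in enumerate(steps):
        eng.advance(int(s - done))
        done = int(s)
        com = (
            eng.system.network_com() if has_network else np.zeros(3)
        )
        d = np.linalg.norm(eng.system.positions[solute] - com, axis=1)
        if first_exit:
            released |= d > Rng
            f[k] = released.mean()
        else:
            f[k] = np.mean(d > Rng)
    return ReleaseCurve(
        times=t_grid,
        f=f,
        n_drug=n_drug,
        replicate_ids=[replicate_id],
        mode=params.mode,
        loading=loading,
        solute_diameter=float(2.0 * system.radii[solute[0]]),
        first_exit=first_exit,
        meta={"seed": params.seed, "Rng": Rng,
              "acceptance_rate": eng.acceptance_rate},
    )


def average_curves(curves: list[ReleaseCurve]) -> ReleaseCurve:
    """Pointwise mean of replicate release curves (identical grids/specs)."""
    if not curves:
        raise ValueError("no curves to average")
    ref = curves[0]
    for c in curves[1:]:
        if len(c.times) != len(ref.times) or not np.allclose(
            c.times, ref.times, rtol=0, atol=0
        ):
            raise ValueError("mismatched time grids")
        if (c.mode, c.loading, c.n_drug) != (ref.mode, ref.loading, ref.n_drug):
            raise ValueError("mismatched release specs")
    ids = [i for c in curves for i in c.replicate_ids]
    return ReleaseCurve(
        times=ref.times.copy(),
        f=np.mean([c.f for c in curves], axis=0),
        n_drug=ref.n_drug,
        replicate_ids=ids,
        mode=ref.mode,
        loading=ref.loading,
        solute_diameter=ref.solute_diameter,
        meta={"averaged": len(curves)},
    )


def run_replicates(
    gel: BeadSystem,
    topology: NetworkTopology,
    params: SimulationParams,
    spec: LoadingSpec,
    Rng: float,
    n_replicates: int,
    base_rng: RNGStream,
) -> ReleaseCurve:
    """Load + release ``n_replicates`` times and average the curves.

    Each replicate gets its own loading stream and propagation seed derived
    from ``base_rng`` so the whole set is reproducible from one seed.
    """
    curves = []
    for r in range(n_replicates):
        child = base_rng.spawn(r)
        loaded = load_solutes(gel, spec, child)
        p = params.replace(seed=child.seed)
        curves.append(
            run_release(
                loaded, topology, p, Rng,
                loading=spec.loading, replicate_id=child.seed,
            )
        )
    return average_curves(curves)
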