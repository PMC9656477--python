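"""Core data containers shared by the builder, engine and analysis modules.

Internal unit system: length in nm, time in ns, energy in kBT.  In these
units diffusion coefficients are nm^2/ns, forces kBT/nm and the harmonic
bond constant kBT/nm^2.  SI values (time step in seconds, temperature in K,
viscosity in Pa s) appear only at the boundary, in :class:`SimulationParams`
and in the Einstein-Stokes conversion.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

#: Boltzmann constant, J/K.
KB = 1.380649e-23

# Bead kind codes.
MONOMER = 0
CROSSLINKER = 1
SOLUTE = 2
KIND_LABELS = {MONOMER: "M", CROSSLINKER: "X", SOLUTE: "S"}
LABEL_KINDS = {v: k for k, v in KIND_LABELS.items()}


class RNGStream:
    """Seeded random-number stream with a draw counter.

    A thin wrapper around :class:`numpy.random.Generator` (PCG64) that
    remembers its seed and counts the scalar draws it has produced, so a
    run's provenance record can state exactly which stream fed it.
    Identical seeds give identical trajectories on a given platform.
    """

    def __init__(self, seed: int):
        if not (0 <= int(seed) < 2**63):
            raise ValueError("seed must be a non-negative 63-bit integer")
        self.seed = int(seed)
        self.draws = 0
        self._gen = np.random.Generator(np.random.PCG64(self.seed))

    def standard_normal(self, size=None) -> np.ndarray | float:
        self.draws += int(np.prod(size)) if size is not None else 1
        return self._gen.standard_normal(size)

    def uniform(self, low=0.0, high=1.0, size=None):
        self.draws += int(np.prod(size)) if size is not None else 1
        return self._gen.uniform(low, high, size)

    def integers(self, low, high=None, size=None):
        self.draws += int(np.prod(size)) if size is not None else 1
        return self._gen.integers(low, high, size)

    def spawn(self, index: int) -> "RNGStream":
        """Derive an independent child stream (used for replicate runs)."""
        return RNGStream((self.seed * 1000003 + 7919 * (index + 1)) % 2**31)


@dataclasses.dataclass
class NetworkTopology:
    """Connectivity of the polymer network.

    bonds is a (B, 2) integer array of bead-index pairs; every chain of
    ``L`` monomer beads contributes ``L + 1`` bonds
    (crosslinker-m1-...-mL-crosslinker).
    """

    bonds: np.ndarray
    ke: float  # elastic constant, kBT/nm^2
    r0: float  # equilibrium bond length, nm
    chain_count: int
    crosslinker_indices: np.ndarray

    def __post_init__(self):
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.crosslinker_indices = np.asarray(
            self.crosslinker_indices, dtype=np.int64
        )
        if np.any(self.bonds[:, 0] == self.bonds[:, 1]):
            raise ValueError("a bond connects a bead to itself")
        key = np.sort(self.bonds, axis=1)
        if len(np.unique(key, axis=0)) != len(key):
            raise ValueError("duplicate bonds in topology")

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def partners_csr(self, n_beads: int) -> tuple[np.ndarray, np.ndarray]:
        """Bonded partners of each bead as a CSR (ptr, idx) pair."""
        deg = np.zeros(n_beads, dtype=np.int64)
        for a, b in self.bonds:
            deg[a] += 1
            deg[b] += 1
        ptr = np.zeros(n_beads + 1, dtype=np.int64)
        np.cumsum(deg, out=ptr[1:])
        idx = np.empty(ptr[-1], dtype=np.int64)
        fill = ptr[:-1].copy()
        for a, b in self.bonds:
            idx[fill[a]] = b
            fill[a] += 1
            idx[fill[b]] = a
            fill[b] += 1
        return ptr, idx


@dataclasses.dataclass
class BeadSystem:
    """Positions, sizes, kinds and free diffusion coefficients of all beads."""

    positions: np.ndarray  # (N, 3) nm
    radii: np.ndarray  # (N,) nm
    kinds: np.ndarray  # (N,) int codes MONOMER/CROSSLINKER/SOLUTE
    D0: np.ndarray  # (N,) nm^2/ns

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.radii = np.ascontiguousarray(self.radii, dtype=np.float64)
        self.kinds = np.ascontiguousarray(self.kinds, dtype=np.int64)
        self.D0 = np.ascontiguousarray(self.D0, dtype=np.float64)
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (N, 3)")
        if not (len(self.radii) == len(self.kinds) == len(self.D0) == n):
            raise ValueError("per-bead arrays must share one length")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def network_mask(self) -> np.ndarray:
        return self.kinds != SOLUTE

    @property
    def solute_mask(self) -> np.ndarray:
        return self.kinds == SOLUTE

    def network_com(self) -> np.ndarray:
        """Centre of mass of the network beads (equal masses)."""
        m = self.network_mask
        if not m.any():
            raise ValueError("system has no network beads")
        return self.positions[m].mean(axis=0)

    def copy(self) -> "BeadSystem":
        return BeadSystem(
            self.positions.copy(),
            self.radii.copy(),
            self.kinds.copy(),
            self.D0.copy(),
        )


@dataclasses.dataclass
class SimulationParams:
    """Propagation parameters.

    dt is stored in seconds (the natural unit in which the time step is
    quoted); everything downstream uses ``dt_ns``.
    """

    dt: float = 3e-12  # s
    T: float = 293.0  # K
    eta: float = 1.002e-3  # Pa s, water at 293 K
    box_side: float = 10_000.0  # nm
    mode: str = "flexible"  # "rigid" | "flexible"
    seed: int = 0
    n_steps: int = 0
    sample_times: np.ndarray | None = None  # ns, strictly increasing

    def __post_init__(self):
        if self.dt <= 0 or self.T <= 0 or self.eta <= 0 or self.box_side <= 0:
            raise ValueError("dt, T, eta and box_side must be positive")
        if self.mode not in ("rigid", "flexible"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.sample_times is not None:
            st = np.asarray(self.sample_times, dtype=np.float64)
            if st.ndim != 1 or np.any(np.diff(st) <= 0):
                raise ValueError("sample_times must be strictly increasing")
            self.sample_times = st

    @property
    def dt_ns(self) -> float:
        return self.dt * 1e9

    def replace(self, **kw) -> "SimulationParams":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass
class StructureReport:
    """Structural descriptors of an (equilibrated) nanogel."""

    Rg: float  # nm
    Rng: float  # nm, geometric radius sqrt(5/3) Rg
    phi: float  # polymer volume fraction inside Rng
    mean_crosslinker_spacing: float  # nm, nearest-neighbour mean
    frac_beyond_Rng: float
    Rcore: float  # nm

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "Rg_nm": [self.Rg],
                "Rng_nm": [self.Rng],
                "phi": [self.phi],
                "mean_crosslinker_spacing_nm": [self.mean_crosslinker_spacing],
                "frac_beyond_Rng": [self.frac_beyond_Rng],
                "Rcore_nm": [self.Rcore],
            }
        ).to_csv(path, index=False)


@dataclasses.dataclass
class DensityProfile:
    """Radial number density about the network centre of mass."""

    bin_edges: np.ndarray  # (nb+1,) nm
    monomer_density: np.ndarray  # (nb,) beads/nm^3
    crosslinker_density: np.ndarray  # (nb,) beads/nm^3

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_density(self) -> np.ndarray:
        return self.monomer_density + self.crosslinker_density

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "r_nm": self.bin_centers,
                "monomer_density_per_nm3": self.monomer_density,
                "crosslinker_density_per_nm3": self.crosslinker_density,
            }
        ).to_csv(path, index=False)


@dataclasses.dataclass
class LoadingSpec:
    """How drug molecules are introduced into the nanogel."""

    n_drug: int = 100
    solute_diameter: float = 1.0  # nm
    R_max: float = 10.65  # nm; Rng for throughout-loading, Rcore for core-loading
    loading: str = "throughout"  # "throughout" | "core"
    max_attempts: int = 1_000_000  # per solute

    def __post_init__(self):
        if self.n_drug < 1:
            raise ValueError("n_drug must be >= 1")
        if self.solute_diameter <= 0 or self.R_max <= 0:
            raise ValueError("solute_diameter and R_max must be positive")
        if self.loading not in ("throughout", "core"):
            raise ValueError(f"unknown loading {self.loading!r}")


@dataclasses.dataclass
class ReleaseCurve:
    """Fraction of drug released versus time, with replicate provenance."""

    times: np.ndarray  # ns
    f: np.ndarray
    n_drug: int
    replicate_ids: list
    mode: str
    loading: str
    solute_diameter: float = float("nan")
    first_exit: bool = True
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.f = np.asarray(self.f, dtype=np.float64)
        if self.times.shape != self.f.shape:
            raise ValueError("times and f must have the same shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.f < -1e-12) or np.any(self.f > 1 + 1e-12):
            raise ValueError("f must lie in [0, 1]")
        # the instantaneous-fraction variant (first_exit=False) may dip
        if self.first_exit and np.any(np.diff(self.f) < -1e-12):
            raise ValueError("f must be non-decreasing")


@dataclasses.dataclass
class DiffusionParams:
    """Free and in-gel diffusion coefficients with the geometry behind them."""

    D0: float  # nm^2/ns
    Dg: float  # nm^2/ns
    phi: float
    Rs: float  # solute radius, nm
    Rp: float  # polymer bead radius, nm
    Rng: float  # nm


@dataclasses.dataclass
class KineticsFit:
    """Result of a power-law / delayed power-law / Weibull fit."""

    model: str  # "power_law" | "delayed_power_law" | "weibull"
    n: float
    k: float
    td: float  # ns; 0 for the plain power law
    R2: float  # on the fitted window
    R2_full: float  # on the whole curve
    window_t: tuple  # (t_min, t_max) ns actually fitted
    window_f: tuple  # (f_min, f_max)
    param_sds: dict = dataclasses.field(default_factory=dict)


def solute_labels(kinds: Sequence[int]) -> list[str]:
    """Kind codes -> one-letter labels used in XYZ output."""
    return [KIND_LABELS[int(k)] for k in kinds]
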