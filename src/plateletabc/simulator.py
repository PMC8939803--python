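"""Stochastic particle model of platelet deposition in a cone-and-plate shear device.

The model tracks individual activated (AP) and non-activated (NAP) platelets
performing a random walk in a shear flow above a discretised deposition
substrate.  A platelet that crosses the lower boundary joins the cell-free
layer over one substrate cell and becomes a deposition candidate; it never
re-enters the bulk.  Candidates deposit stochastically through three
channels -- adhesion of AP onto free substrate (seeding a new cluster),
aggregation of AP/NAP beside an existing cluster, and deposition on top of a
cluster -- all attenuated by the local density of deposited albumin, which
competes with platelets for the substrate.  Albumin itself is so abundant
that its surface density follows a deterministic mean-field saturation law.

Observables are the number of aggregate clusters per mm^2, their mean size
(in substrate cells; one cell holds one deposited platelet), and the number
of non-activated platelets per microlitre still in suspension, reported on a
fixed observation grid.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PARAM_NAMES",
    "DepositionParams",
    "DeviceConfig",
    "SimulationState",
    "DepositionTimeSeries",
    "initial_state",
    "step_transport",
    "step_deposition",
    "cluster_statistics",
    "simulate",
]

#: Canonical ordering of the seven model parameters, used whenever a
#: parameter vector is exchanged as a flat array (priors, posteriors, CSV).
PARAM_NAMES = (
    "adhesion_rate",
    "aggregation_rate",
    "top_rate",
    "albumin_rate",
    "albumin_attenuation",
    "velocity_ap",
    "velocity_nap",
)


@dataclasses.dataclass(frozen=True)
class DepositionParams:
    """The seven subject-specific model parameters.

    Parameters
    ----------
    adhesion_rate : float
        Rate (1/s) at which a candidate AP deposits on platelet-free
        substrate, seeding a new cluster.
    aggregation_rate : float
        Rate (1/s) at which a candidate platelet (AP or NAP) deposits on a
        free cell adjacent to an existing cluster.
    top_rate : float
        Rate (1/s) of deposition on top of an already occupied cell.
    albumin_rate : float
        Albumin deposition rate (1/s), per free albumin site in a cell.
    albumin_attenuation : float
        Attenuation factor (per albumin particle per cell) multiplying the
        deposited-albumin density in the exponential that damps platelet
        adhesion and aggregation.
    velocity_ap, velocity_nap : float
        Characteristic vertical speeds (m/s) of activated and non-activated
        platelets in the bulk.
    """

    adhesion_rate: float
    aggregation_rate: float
    top_rate: float
    albumin_rate: float
    albumin_attenuation: float
    velocity_ap: float
    velocity_nap: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "DepositionParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters, got shape {theta.shape}")
        return cls(**dict(zip(PARAM_NAMES, theta.tolist())))


@dataclasses.dataclass(frozen=True)
class DeviceConfig:
    """Geometry, discretisation and initial concentrations of one run.

    Defaults describe the physical device: a 0.82 mm gap above a 1 x 1 mm
    observation window, substrate cells of 5 um^2 (one platelet footprint),
    at most 100 000 albumin particles per cell, and typical whole-blood
    concentrations of non-activated platelets, activated platelets and
    albumin.  ``scale`` shrinks the window linearly (area and particle
    counts by ``scale**2``) so that a run takes seconds instead of minutes;
    per-area observables are scale-invariant in the mean.
    """

    height: float = 820.0            # um, gap between substrate and cone
    window_side: float = 1000.0      # um, side of the observation window
    shear_rate: float = 100.0        # 1/s, imposed by the rotating cone
    dt: float = 0.01                 # s, explicit time step
    cell_area: float = 5.0           # um^2, substrate cell = platelet footprint
    rho_max: float = 100_000.0       # albumin particles per cell at saturation
    init_nap: float = 172_200.0      # non-activated platelets per ul
    init_ap: float = 4_808.0         # activated platelets per ul
    init_albumin: float = 2.69e13    # albumin per ul (bulk; mean-field reservoir)
    obs_times: tuple[float, ...] = (0.0, 20.0, 120.0, 300.0)
    end_time: float = 300.0          # s
    scale: float = 0.1               # linear window scale factor
    seed: int | None = None
    connectivity: int = 8            # cluster adjacency: 4 or 8

    def __post_init__(self) -> None:
        for name in ("height", "window_side", "dt", "cell_area", "scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.rho_max < 1:
            raise ValueError("rho_max must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        ts = tuple(float(t) for t in self.obs_times)
        if any(t < 0 or t > self.end_time for t in ts):
            raise ValueError("obs_times must lie in [0, end_time]")
        if list(ts) != sorted(ts):
            raise ValueError("obs_times must be sorted")
        object.__setattr__(self, "obs_times", ts)

    # -- derived geometry ------------------------------------------------
    @property
    def cell_side(self) -> float:
        """Side (um) of a square substrate cell."""
        return math.sqrt(self.cell_area)

    @property
    def width(self) -> float:
        """Scaled window side (um)."""
        return self.window_side * self.scale

    @property
    def grid_shape(self) -> tuple[int, int]:
        n = max(1, round(self.width / self.cell_side))
        return (n, n)

    @property
    def volume_ul(self) -> float:
        """Simulated blood volume in microlitres (1 ul = 1e9 um^3)."""
        return self.width**2 * self.height * 1e-9

    @property
    def substrate_area_mm2(self) -> float:
        nx, ny = self.grid_shape
        return nx * ny * self.cell_area * 1e-6

    @property
    def n_steps(self) -> int:
        return max(1, round(self.end_time / self.dt))


@dataclasses.dataclass
class SimulationState:
    """Mutable state advanced by :func:`step_transport` / :func:`step_deposition`.

    Bulk platelets are stored in one position array with a parallel species
    mask; candidates trapped at the cell-free layer and the substrate are
    per-cell grids.  Conservation (bulk + trapped + deposited = initial, per
    species) holds after every step.
    """

    positions: np.ndarray        # (n, 3) x, y, z in um, bulk platelets
    is_ap: np.ndarray            # (n,) bool, species of each bulk platelet
    trapped_ap: np.ndarray       # (ny, nx) int, CFL candidates per cell
    trapped_nap: np.ndarray
    substrate: np.ndarray        # (ny, nx) int, deposited-platelet stack height
    rho_al: np.ndarray           # (ny, nx) float, deposited albumin per cell
    deposited_ap: int
    deposited_nap: int
    init_ap: int
    init_nap: int
    t: float
    rng: np.random.Generator
    #: cells with >= 1 occupied neighbor under the configured adjacency
    #: (periodic wrap); grown incrementally since deposition is irreversible.
    neighbor_mask: np.ndarray | None = None

    def bulk_counts(self) -> tuple[int, int]:
        n_ap = int(self.is_ap.sum())
        return n_ap, int(len(self.is_ap) - n_ap)

    def check_conservation(self) -> None:
        b_ap, b_nap = self.bulk_counts()
        tot_ap = b_ap + int(self.trapped_ap.sum()) + self.deposited_ap
        tot_nap = b_nap + int(self.trapped_nap.sum()) + self.deposited_nap
        if tot_ap != self.init_ap or tot_nap != self.init_nap:
            raise AssertionError(
                f"platelet conservation violated: AP {tot_ap}/{self.init_ap}, "
                f"NAP {tot_nap}/{self.init_nap}"
            )


@dataclasses.dataclass
class DepositionTimeSeries:
    """The per-subject observable triple on the observation time grid."""

    times: np.ndarray              # s
    n_clusters: np.ndarray         # clusters per mm^2
    mean_cluster_size: np.ndarray  # cells per cluster (1 cell = one platelet footprint)
    n_platelet: np.ndarray         # non-activated platelets per ul in suspension
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.n_clusters = np.asarray(self.n_clusters, dtype=float)
        self.mean_cluster_size = np.asarray(self.mean_cluster_size, dtype=float)
        self.n_platelet = np.asarray(self.n_platelet, dtype=float)
        n = len(self.times)
        if not (len(self.n_clusters) == len(self.mean_cluster_size) == len(self.n_platelet) == n):
            raise ValueError("all observable arrays must have the length of `times`")
        for name in ("n_clusters", "mean_cluster_size", "n_platelet"):
            arr = getattr(self, name)
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite and >= 0")

    def as_vector(self) -> np.ndarray:
        """Flatten to [n_clusters(t...), mean_cluster_size(t...), n_platelet(t...)]."""
        return np.concatenate([self.n_clusters, self.mean_cluster_size, self.n_platelet])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepositionTimeSeries):
            return NotImplemented
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.n_clusters, other.n_clusters)
            and np.array_equal(self.mean_cluster_size, other.mean_cluster_size)
            and np.array_equal(self.n_platelet, other.n_platelet)
        )


# ---------------------------------------------------------------------------
# transport
# ---------------------------------------------------------------------------

def _advance_positions(
    positions: np.ndarray,
    speeds_um: np.ndarray,
    shear_rate: float,
    height: float,
    width: float,
    dt: float,
    rng: np.random.Generator | None,
    *,
    s: np.ndarray | None = None,
    lam: np.ndarray | None = None,
    r: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One random-walk + shear step for all bulk platelets.

    Each platelet draws one half-normal magnitude |s| shared by its vertical
    and horizontal jump, a sign for the vertical direction and a uniform
    planar angle.  x, y wrap periodically; z bounces back at the top; a
    platelet whose z falls below the substrate is flagged as trapped.

    Returns ``(new_positions, trapped_mask)``; trapped rows carry their
    wrapped landing (x, y).  The keyword draws exist so that tests can force
    specific random variates.
    """
    n = len(positions)
    if n == 0:
        return positions, np.zeros(0, dtype=bool)
    if s is None:
        s = rng.standard_normal(n)
    if lam is None:
        lam = rng.integers(0, 2, n) * 2 - 1
    if r is None:
        r = rng.random(n)
    radial = speeds_um * np.abs(s) * dt
    angle = 2.0 * np.pi * r
    out = np.empty_like(positions)
    # shear advection uses z at the start of the step
    out[:, 0] = positions[:, 0] + radial * np.cos(angle) + shear_rate * positions[:, 2] * dt
    out[:, 1] = positions[:, 1] + radial * np.sin(angle)
    out[:, 2] = positions[:, 2] + lam * radial
    if not np.all(np.isfinite(out)):
        bad = int(np.flatnonzero(~np.all(np.isfinite(out), axis=1))[0])
        raise FloatingPointError(f"non-finite position for particle index {bad}")
    out[:, 0] %= width
    out[:, 1] %= width
    z = out[:, 2]
    over = z > height
    if over.any():
        # guard clip: one mirror image is enough at sane dt
        z[over] = np.clip(2.0 * height - z[over], 0.0, height)
    return out, z < 0


def step_transport(
    state: SimulationState, params: DepositionParams, config: DeviceConfig
) -> SimulationState:
    """Advance every bulk platelet by one time step (in place).

    Platelets crossing the substrate plane are moved from the bulk into the
    trapped-candidate grid of the cell under their wrapped (x, y).
    """
    speeds = np.where(state.is_ap, params.velocity_ap, params.velocity_nap) * 1e6  # m/s -> um/s
    pos, trapped = _advance_positions(
        state.positions, speeds, config.shear_rate, config.height, config.width,
        config.dt, state.rng,
    )
    if trapped.any():
        ny, nx = state.trapped_ap.shape
        side = config.cell_side
        tx = np.minimum((pos[trapped, 0] / side).astype(int), nx - 1)
        ty = np.minimum((pos[trapped, 1] / side).astype(int), ny - 1)
        ap_t = state.is_ap[trapped]
        np.add.at(state.trapped_ap, (ty[ap_t], tx[ap_t]), 1)
        np.add.at(state.trapped_nap, (ty[~ap_t], tx[~ap_t]), 1)
        keep = ~trapped
        state.positions = pos[keep]
        state.is_ap = state.is_ap[keep]
    else:
        state.positions = pos
    state.t += config.dt
    return state


# ---------------------------------------------------------------------------
# deposition
# ---------------------------------------------------------------------------

def _clamped_prob(rate: float, dt: float, atten: np.ndarray | float = 1.0) -> np.ndarray | float:
    p = rate * dt * atten
    if np.any(np.asarray(p) < 0):
        raise ValueError("negative deposition probability (invariant breach upstream)")
    return np.minimum(p, 1.0)


_NEIGHBOR_OFFSETS = {
    4: ((0, 1), (0, -1), (1, 0), (-1, 0)),
    8: ((0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)),
}


def _neighbor_occupied(substrate: np.ndarray, connectivity: int) -> np.ndarray:
    """Boolean grid: cell has at least one occupied neighbor (periodic wrap)."""
    occ = substrate > 0
    out = np.zeros_like(occ)
    for dy, dx in _NEIGHBOR_OFFSETS[connectivity]:
        out |= np.roll(occ, (dy, dx), axis=(0, 1))
    return out


def _mark_neighbors(mask: np.ndarray, flat_idx: np.ndarray, connectivity: int) -> None:
    """Set the neighbor flags of newly occupied cells (periodic wrap), in place."""
    ny, nx = mask.shape
    y, x = np.divmod(flat_idx, nx)
    for dy, dx in _NEIGHBOR_OFFSETS[connectivity]:
        mask[(y + dy) % ny, (x + dx) % nx] = True


def step_deposition(
    state: SimulationState, params: DepositionParams, config: DeviceConfig
) -> SimulationState:
    """One deposition sweep over the substrate grid (in place).

    Order within the sweep: albumin mean-field update, AP adhesion on free
    cells, AP/NAP aggregation beside occupied cells, AP/NAP deposition on
    top of occupied cells.  Every candidate attempts its channel
    independently (a binomial draw per cell); failures stay trapped.
    """
    dt = config.dt
    rng = state.rng
    # (a) albumin: mean-field saturation, clamped so rho_al stays <= rho_max
    pf = _clamped_prob(params.albumin_rate, dt)
    if pf > 0:
        state.rho_al += pf * (config.rho_max - state.rho_al)

    if not (state.trapped_ap.any() or state.trapped_nap.any()):
        return state
    if state.neighbor_mask is None:
        state.neighbor_mask = _neighbor_occupied(state.substrate, config.connectivity)

    sub = state.substrate.ravel()
    t_ap = state.trapped_ap.ravel()
    t_nap = state.trapped_nap.ravel()
    nb = state.neighbor_mask.ravel()

    def attenuation(idx: np.ndarray) -> np.ndarray:
        return np.exp(-params.albumin_attenuation * state.rho_al.ravel()[idx])

    def deposit(idx: np.ndarray, trapped: np.ndarray, prob, attr: str) -> np.ndarray:
        """Binomial deposition of trapped candidates at `idx`; returns newly occupied."""
        was_free = sub[idx] == 0
        k = rng.binomial(trapped[idx], prob)
        sub[idx] += k
        trapped[idx] -= k
        setattr(state, attr, getattr(state, attr) + int(k.sum()))
        return idx[was_free & (k > 0)]

    # (b) adhesion: AP over platelet-free cells seed new clusters
    if params.adhesion_rate > 0:
        idx = np.flatnonzero((t_ap > 0) & (sub == 0))
        if idx.size:
            q = np.minimum(params.adhesion_rate * dt * attenuation(idx), 1.0)
            new = deposit(idx, t_ap, q, "deposited_ap")
            if new.size:
                _mark_neighbors(state.neighbor_mask, new, config.connectivity)

    # (c) aggregation: AP and NAP beside an occupied cell
    if params.aggregation_rate > 0:
        for trapped, attr in ((t_ap, "deposited_ap"), (t_nap, "deposited_nap")):
            idx = np.flatnonzero((sub == 0) & nb & (trapped > 0))
            if idx.size:
                rr = np.minimum(params.aggregation_rate * dt * attenuation(idx), 1.0)
                new = deposit(idx, trapped, rr, attr)
                if new.size:
                    _mark_neighbors(state.neighbor_mask, new, config.connectivity)

    # (d) on top of an existing cluster (stack height grows, no new cells)
    if params.top_rate > 0:
        pt = min(params.top_rate * dt, 1.0)
        for trapped, attr in ((t_ap, "deposited_ap"), (t_nap, "deposited_nap")):
            idx = np.flatnonzero((trapped > 0) & (sub > 0))
            if idx.size:
                deposit(idx, trapped, pt, attr)
    return state


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def cluster_statistics(
    substrate: np.ndarray, config: DeviceConfig
) -> tuple[float, float]:
    """Cluster count per mm^2 and mean cluster size (cells) of the substrate.

    Clusters are connected components of occupied cells under the
    configured 4- or 8-adjacency, with periodic wrap in both directions
    (consistent with the periodic transport boundaries).  An empty
    substrate returns ``(0.0, 0.0)`` by convention.
    """
    substrate = np.asarray(substrate)
    if substrate.ndim != 2 or np.any(substrate < 0):
        raise ValueError("substrate must be a 2-D grid of non-negative stack heights")
    occ = substrate > 0
    n_occ = int(occ.sum())
    if n_occ == 0:
        return 0.0, 0.0
    structure = (
        np.ones((3, 3), dtype=int)
        if config.connectivity == 8
        else np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    )
    labels, n_lab = ndimage.label(occ, structure=structure)

    # merge labels across the periodic seam with union-find
    parent = np.arange(n_lab + 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        if a and b:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

    ny, nx = labels.shape
    deltas = (0,) if config.connectivity == 4 else (-1, 0, 1)
    if ny > 1:
        for j in range(nx):
            if labels[0, j]:
                for d in deltas:
                    union(labels[0, j], labels[ny - 1, (j + d) % nx])
    if nx > 1:
        for i in range(ny):
            if labels[i, 0]:
                for d in deltas:
                    union(labels[i, 0], labels[(i + d) % ny, nx - 1])

    roots = {find(l) for l in range(1, n_lab + 1)}
    n_comp = len(roots)
    # mean component size = occupied cells / number of components
    return n_comp / config.substrate_area_mm2, n_occ / n_comp


# ---------------------------------------------------------------------------
# full forward simulation
# ---------------------------------------------------------------------------

def initial_state(config: DeviceConfig, rng: np.random.Generator) -> SimulationState:
    """Draw the initial bulk platelet population uniformly in the scaled box."""
    n_nap = round(config.init_nap * config.volume_ul)
    n_ap = round(config.init_ap * config.volume_ul)
    if n_nap + n_ap == 0:
        raise ValueError(
            "zero platelets after scaling; increase `scale` (or the initial concentrations)"
        )
    n = n_nap + n_ap
    positions = np.empty((n, 3))
    positions[:, 0] = rng.random(n) * config.width
    positions[:, 1] = rng.random(n) * config.width
    positions[:, 2] = rng.random(n) * config.height
    is_ap = np.zeros(n, dtype=bool)
    is_ap[:n_ap] = True
    shape = config.grid_shape[::-1]  # (ny, nx)
    return SimulationState(
        positions=positions,
        is_ap=is_ap,
        trapped_ap=np.zeros(shape, dtype=np.int64),
        trapped_nap=np.zeros(shape, dtype=np.int64),
        substrate=np.zeros(shape, dtype=np.int64),
        rho_al=np.zeros(shape, dtype=float),
        deposited_ap=0,
        deposited_nap=0,
        init_ap=n_ap,
        init_nap=n_nap,
        t=0.0,
        rng=rng,
    )


def _warn_on_clamping(params: DepositionParams, config: DeviceConfig) -> None:
    channels = {
        "adhesion_rate": params.adhesion_rate,
        "aggregation_rate": params.aggregation_rate,
        "top_rate": params.top_rate,
        "albumin_rate": params.albumin_rate,
    }
    clamped = [name for name, rate in channels.items() if rate * config.dt > 1.0]
    if clamped:
        warnings.warn(
            f"per-step probability clamped to 1 for {clamped} at dt={config.dt}; "
            "rates above 1/dt are indistinguishable",
            RuntimeWarning,
            stacklevel=3,
        )


def simulate(
    params: DepositionParams,
    config: DeviceConfig,
    seed: int | np.random.Generator | None = None,
    engine: str = "fast",
) -> DepositionTimeSeries:
    """Forward-simulate the deposition model and record the observable triple.

    Alternates one transport and one deposition sweep per time step from
    t = 0 to ``config.end_time`` and evaluates (clusters per mm^2, mean
    cluster size, NAP per ul in suspension) at each observation time.
    Trapped-but-undeposited platelets count as still in suspension, so
    ``n_platelet`` tracks (initial - deposited) NAP.  Fully reproducible
    given the seed.

    ``engine="fast"`` runs the compiled kernel (default; falls back to the
    pure-numpy engine when numba is unavailable); ``engine="reference"``
    loops the :func:`step_transport` / :func:`step_deposition` functions
    directly.  The engines implement the same physics on different random
    streams, so they agree in distribution but not draw-for-draw.
    """
    if engine not in ("fast", "reference"):
        raise ValueError("engine must be 'fast' or 'reference'")
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _warn_on_clamping(params, config)

    n_steps = config.n_steps
    if abs(n_steps * config.dt - config.end_time) > 1e-9 * max(1.0, config.end_time):
        warnings.warn(
            f"end_time {config.end_time} is not a multiple of dt {config.dt}; "
            f"running {n_steps} steps",
            RuntimeWarning,
            stacklevel=2,
        )
    state = initial_state(config, rng)
    obs_steps = [round(t / config.dt) for t in config.obs_times]

    from ._kernel import HAVE_NUMBA

    if engine == "fast" and HAVE_NUMBA:
        times, n_cl, sz, n_pl = _run_fast(state, params, config, obs_steps)
    else:
        times, n_cl, sz, n_pl = _run_reference(state, params, config, obs_steps)
    meta = {
        "params": dict(zip(PARAM_NAMES, params.as_array().tolist())),
        "init_nap_per_ul": config.init_nap,
        "init_ap_per_ul": config.init_ap,
        "init_albumin_per_ul": config.init_albumin,
        "scale": config.scale,
        "dt": config.dt,
        "seed": None if isinstance(seed, np.random.Generator) else seed,
    }
    return DepositionTimeSeries(
        times=np.array(times),
        n_clusters=np.array(n_cl),
        mean_cluster_size=np.array(sz),
        n_platelet=np.array(n_pl),
        meta=meta,
    )


def _run_reference(
    state: SimulationState,
    params: DepositionParams,
    config: DeviceConfig,
    obs_steps: list[int],
) -> tuple[list, list, list, list]:
    times, n_cl, sz, n_pl = [], [], [], []

    def record(step: int) -> None:
        c, s = cluster_statistics(state.substrate, config)
        times.append(step * config.dt)
        n_cl.append(c)
        sz.append(s)
        n_pl.append((state.init_nap - state.deposited_nap) / config.volume_ul)

    pending = list(obs_steps)
    if pending and pending[0] == 0:
        record(0)
        pending.pop(0)
    for step in range(1, config.n_steps + 1):
        step_transport(state, params, config)
        step_deposition(state, params, config)
        if pending and step == pending[0]:
            record(step)
            pending.pop(0)
    return times, n_cl, sz, n_pl


def _run_fast(
    state: SimulationState,
    params: DepositionParams,
    config: DeviceConfig,
    obs_steps: list[int],
) -> tuple[list, list, list, list]:
    from ._kernel import _run

    times, n_cl, sz, n_pl = [], [], [], []
    pending = [s for s in obs_steps if s >= 1]
    if obs_steps and obs_steps[0] == 0:
        times.append(0.0)
        n_cl.append(0.0)
        sz.append(0.0)
        n_pl.append(state.init_nap / config.volume_ul)
    kernel_seed = int(state.rng.integers(2**31))
    snap_sub, snap_dep_nap, _ = _run(
        state.positions,
        state.is_ap,
        params.velocity_ap * 1e6,
        params.velocity_nap * 1e6,
        config.shear_rate,
        config.height,
        config.width,
        config.cell_side,
        state.substrate.shape[0],
        state.substrate.shape[1],
        params.adhesion_rate,
        params.aggregation_rate,
        params.top_rate,
        params.albumin_rate,
        params.albumin_attenuation,
        config.rho_max,
        config.dt,
        config.n_steps,
        np.asarray(pending, dtype=np.int64),
        config.connectivity == 8,
        kernel_seed,
    )
    for j, step in enumerate(pending):
        c, s = cluster_statistics(snap_sub[j], config)
        times.append(step * config.dt)
        n_cl.append(c)
        sz.append(s)
        n_pl.append((state.init_nap - int(snap_dep_nap[j])) / config.volume_ul)
    return times, n_cl, sz, n_pl
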