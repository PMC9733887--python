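"""Spatial network construction for the branching model.

Neurons are placed uniformly at random on a periodic square of linear size
``L = 2 * sqrt(N_N) * d_N`` (the ideal-gas relation for a 2D Poisson process
with nearest-neighbour spacing ``d_N``), excluding a small dead zone around
each electrode.  Every neuron is connected to all neighbours within a hard
cutoff ``d_max``; connection weights decay as a Gaussian of the periodic
distance and are normalised to sum to one per source neuron.

Units: all lengths in micrometres (um), densities in neurons per um^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "GeometryConfig",
    "NetworkTopology",
    "system_size",
    "connection_radius",
    "periodic_distance",
    "place_neurons",
    "build_connectivity",
]

#: Default nearest-neighbour spacing between neurons (um).
DEFAULT_D_N = 50.0
#: Default dead-zone radius around each electrode, d_N / 5 (um).
DEFAULT_DEAD_ZONE = DEFAULT_D_N / 5.0


def system_size(n_neurons: int, d_n: float) -> float:
    """Linear size L (um) of the periodic square holding ``n_neurons``.

    For uniformly (Poisson) distributed neurons with mean nearest-neighbour
    distance ``d_n`` the ideal-gas argument gives ``L = 2 * sqrt(N) * d_n``,
    equivalently a density ``rho = 1 / (4 d_n^2)``.

    Parameters
    ----------
    n_neurons : int
        Number of neurons, >= 1.
    d_n : float
        Mean nearest-neighbour distance in um, > 0.
    """
    if n_neurons < 1:
        raise ValueError(f"n_neurons must be >= 1, got {n_neurons}")
    if d_n <= 0:
        raise ValueError(f"d_n must be > 0, got {d_n}")
    return 2.0 * np.sqrt(n_neurons) * d_n


def connection_radius(k: float, rho: float) -> float:
    """Radius (um) of a disk that contains on average ``k`` neurons.

    ``d_max = sqrt(k / (pi * rho))`` with ``rho`` in neurons / um^2.  Used to
    pick the hard connectivity cutoff that yields mean out-degree ``k``.
    """
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    if rho <= 0:
        raise ValueError(f"rho must be > 0, got {rho}")
    return float(np.sqrt(k / (np.pi * rho)))


def periodic_distance(a: np.ndarray, b: np.ndarray, box: float) -> np.ndarray:
    """Minimum-image Euclidean distance between points on a periodic square.

    ``a`` and ``b`` broadcast against each other; the last axis holds (x, y).
    """
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    d = np.minimum(d, box - d)
    return np.sqrt((d ** 2).sum(axis=-1))


@dataclass
class GeometryConfig:
    """Geometry of the neuron sheet.

    Attributes
    ----------
    n_neurons : int
        Number of neurons N_N.
    inter_neuron_distance : float
        Mean nearest-neighbour spacing d_N in um; fixes the density
        ``rho = 1/(4 d_N^2)`` and the system size.
    electrode_positions : ndarray, shape (n_e, 2)
        Electrode coordinates in um.  Electrodes are placed *first*; neuron
        placement then avoids their dead zones.
    dead_zone_radius : float
        Exclusion radius around each electrode in um (no neuron closer).
    seed : int
        Seed for the placement RNG.
    """

    n_neurons: int
    inter_neuron_distance: float = DEFAULT_D_N
    electrode_positions: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2))
    )
    dead_zone_radius: float = DEFAULT_DEAD_ZONE
    seed: int = 0

    @property
    def system_size(self) -> float:
        return system_size(self.n_neurons, self.inter_neuron_distance)

    @property
    def density(self) -> float:
        """Neurons per um^2: rho = N / L^2 = 1 / (4 d_N^2)."""
        return self.n_neurons / self.system_size ** 2


def place_neurons(cfg: GeometryConfig, max_attempts: int = 10_000_000) -> np.ndarray:
    """Sample neuron positions uniformly on [0, L)^2 outside all dead zones.

    Rejection sampling: a candidate inside any electrode's dead zone is
    discarded and redrawn.  Raises ``RuntimeError`` if ``max_attempts``
    candidates are exhausted (dead zones covering too much area).
    """
    L = cfg.system_size
    elec = np.asarray(cfg.electrode_positions, dtype=float).reshape(-1, 2)
    rng = np.random.default_rng(cfg.seed)
    if len(elec) == 0:
        return rng.uniform(0.0, L, size=(cfg.n_neurons, 2))

    out = np.empty((cfg.n_neurons, 2))
    n_placed = 0
    attempts = 0
    while n_placed < cfg.n_neurons:
        n_draw = min(cfg.n_neurons - n_placed + 64, max_attempts - attempts)
        if n_draw <= 0:
            raise RuntimeError(
                f"neuron placement did not terminate after {max_attempts} "
                "attempts; dead zones cover too much area"
            )
        cand = rng.uniform(0.0, L, size=(n_draw, 2))
        attempts += n_draw
        # distance of each candidate to its nearest electrode (minimum image)
        dmin = periodic_distance(cand[:, None, :], elec[None, :, :], L).min(axis=1)
        ok = cand[dmin >= cfg.dead_zone_radius]
        n_take = min(len(ok), cfg.n_neurons - n_placed)
        out[n_placed : n_placed + n_take] = ok[:n_take]
        n_placed += n_take
    return out


@dataclass
class NetworkTopology:
    """Distance-sorted, weight-normalised connectivity in CSR-like layout.

    ``targets[indptr[i]:indptr[i+1]]`` are neuron ``i``'s targets sorted
    ascending by periodic distance (ties broken by neuron index); ``weights``
    and ``distances`` are aligned with ``targets``.  Weights per source sum
    to 1.  The sort order is load-bearing: the simulator's coalescence
    fallback walks the list in this order, and the fast sampler relies on the
    weights being non-increasing along each row.
    """

    positions: np.ndarray  # (N, 2) um
    indptr: np.ndarray  # (N+1,) int64
    targets: np.ndarray  # (E,) int32
    weights: np.ndarray  # (E,) float64, row-normalised
    distances: np.ndarray  # (E,) float64 um
    box_size: float  # L, um
    sigma: float  # um
    d_max: float  # um

    @property
    def n_neurons(self) -> int:
        return len(self.positions)

    @property
    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    @property
    def mean_degree(self) -> float:
        return float(self.degrees.mean())

    def targets_of(self, i: int) -> np.ndarray:
        return self.targets[self.indptr[i] : self.indptr[i + 1]]

    def weights_of(self, i: int) -> np.ndarray:
        return self.weights[self.indptr[i] : self.indptr[i + 1]]


def build_connectivity(
    positions: np.ndarray, d_max: float, sigma: float, box_size: float | None = None
) -> NetworkTopology:
    """Connect every neuron to all neighbours within ``d_max``.

    Weights are Gaussian in the periodic distance,
    ``w_ij = exp(-d_ij^2 / 2 sigma^2) / Omega_i`` with ``Omega_i`` the
    per-source normaliser, so each row sums to one.  ``sigma`` sets the
    effective reach of recurrent activation; ``d_max`` is a hard cutoff
    applied *before* normalisation.

    Parameters
    ----------
    positions : (N, 2) array, um, on [0, L)^2.
    d_max : hard connection cutoff, um; must satisfy d_max < L/2 so the
        minimum-image distance is unambiguous.
    sigma : Gaussian decay length, um, > 0.
    box_size : L in um; inferred as 2*sqrt(N)*d_N only if given explicitly
        (there is no reliable way to infer it, so it is required in practice;
        ``None`` raises).
    """
    positions = np.asarray(positions, dtype=float)
    if box_size is None:
        raise ValueError("box_size (L, um) must be provided")
    L = float(box_size)
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if not d_max < L / 2:
        raise ValueError(
            f"d_max={d_max} must be < L/2={L / 2} (minimum-image validity)"
        )
    n = len(positions)

    tree = cKDTree(positions, boxsize=L)
    pairs = tree.query_pairs(d_max, output_type="ndarray").astype(np.int32)
    # both directions: i -> j and j -> i
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    del pairs
    d = periodic_distance(positions[src], positions[dst], L)

    # sort rows by (source, distance, target index) — deterministic tie-break
    order = np.lexsort((dst, d, src))
    src, dst, d = src[order], dst[order], d[order]
    del order

    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    indptr = np.cumsum(indptr)

    w = np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    # per-row normalisation Omega_i (isolated neurons have empty rows)
    row_sums = np.bincount(src, weights=w, minlength=n)
    row_sums[row_sums == 0.0] = 1.0
    w = w / row_sums[src]

    return NetworkTopology(
        positions=positions,
        indptr=indptr,
        targets=dst.astype(np.int32),
        weights=w,
        distances=d,
        box_size=L,
        sigma=float(sigma),
        d_max=float(d_max),
    )
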