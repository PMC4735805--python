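"""Lattice random-walk simulation of a regulator binding clustered channels.

A diffusing regulatory molecule (the "ligate", e.g. calmodulin) moves on a
3D lattice inside a rectangular cuboid spanning the region around one
Nav1.5 channel cluster.  The lattice pitch is 33 nm (the estimated
pore-to-pore distance between channels); the footprint is the average
inter-cluster distance (1,066 nm -> 32 x 32 steps) and the height 16
steps.  Immobilized channels sit on the z = 0 face, either packed into a
compact cluster or spread evenly.  At 6 uM ligate, the cuboid holds 2,127
molecules.

Update rule (one time step, three phases):

1. Move: every free ligate moves to one of the 6 axis neighbours, chosen
   with weight 1 for each in-domain neighbour except channel sites, whose
   weight is multiplied by the attraction factor whether or not the
   channel is occupied (weights renormalized; boundaries act by excluding
   outward moves).  Moves are mutually independent; any number of ligates
   may share a site.
2. Bind: for every unoccupied channel, the free ligates now at its site
   attempt to bind in index order, each succeeding with ``p_bind``; the
   first success occupies the channel.
3. Release: every bound ligate dissociates with ``p_unbind``, remaining
   at the channel site as a free molecule; it moves off on the next step
   and cannot rebind within the release step.

A channel binds at most one ligate; site occupancy is otherwise
unrestricted.  The dissociation constant is read out from the equilibrated
tail of the bound-count trace as
Kd = [free ligate] * (free channels) / (bound channels), with the free
ligate concentration computed from counts over the cuboid volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WalkConfig",
    "WalkState",
    "KdEstimate",
    "n_ligate_from_concentration",
    "init_state",
    "step_walk",
    "run_walk",
    "estimate_kd",
    "calibrate_probabilities",
    "compare_arrangements",
]

AVOGADRO = 6.02214076e23
_NM3_TO_L = 1e-24

_ARRANGEMENTS = ("clustered", "distributed")


@dataclass
class WalkConfig:
    step_nm: float = 33.0
    domain_xy_nm: float = 1066.0
    nx: int | None = None  # defaults to round(domain_xy / step) = 32
    ny: int | None = None
    nz: int = 16
    n_ligate: int = 2127
    n_channels: int = 44
    arrangement: str = "clustered"
    p_bind: float = 0.5
    p_unbind: float = 0.001
    attraction: float = 4.0
    n_steps: int = 500
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nx is None:
            self.nx = int(round(self.domain_xy_nm / self.step_nm))
        if self.ny is None:
            self.ny = int(round(self.domain_xy_nm / self.step_nm))
        if not (0.0 <= self.p_bind <= 1.0 and 0.0 <= self.p_unbind <= 1.0):
            raise ValueError("p_bind and p_unbind must be in [0, 1]")
        if self.attraction < 1.0:
            raise ValueError("attraction must be >= 1")
        if self.arrangement not in _ARRANGEMENTS:
            raise ValueError(f"arrangement must be one of {_ARRANGEMENTS}")
        if self.n_channels > self.nx * self.ny:
            raise ValueError("more channels than face sites")
        if min(self.nx, self.ny, self.nz) < 2:
            raise ValueError("lattice must be at least 2 sites in each direction")

    @property
    def volume_nm3(self) -> float:
        return (self.nx * self.step_nm) * (self.ny * self.step_nm) * (self.nz * self.step_nm)

    def concentration_nM(self, count: float) -> float:
        """Concentration (nM) of `count` molecules in the cuboid."""
        return count / (AVOGADRO * self.volume_nm3 * _NM3_TO_L) * 1e9


def n_ligate_from_concentration(concentration_uM: float, config: WalkConfig) -> int:
    """Molecule count for a molar concentration in the cuboid volume.

    6 uM in the default 1,056 x 1,056 x 528 nm cuboid gives 2,127,
    the default ligate count.
    """
    return int(round(concentration_uM * 1e-6 * AVOGADRO * config.volume_nm3 * _NM3_TO_L))


def _channel_sites(config: WalkConfig) -> np.ndarray:
    """(n_channels, 2) face coordinates for the requested arrangement."""
    n, nx, ny = config.n_channels, config.nx, config.ny
    if n == 0:
        return np.zeros((0, 2), dtype=int)
    k = int(np.ceil(np.sqrt(n)))
    if config.arrangement == "distributed":
        xs = np.floor((np.arange(k) + 0.5) * nx / k).astype(int)
        ys = np.floor((np.arange(k) + 0.5) * ny / k).astype(int)
    else:  # clustered: compact k x k block at 1-site pitch, centered
        xs = np.arange(k) + (nx - k) // 2
        ys = np.arange(k) + (ny - k) // 2
    grid = np.array([(x, y) for y in ys for x in xs])
    return grid[:n]


@dataclass
class WalkState:
    """Ligate positions, channel sites on the z = 0 face, and occupancy."""

    positions: np.ndarray  # (n_ligate, 3) int, columns (x, y, z)
    channel_xy: np.ndarray  # (n_channels, 2) int
    bound_to: np.ndarray  # (n_ligate,) channel index or -1
    channel_map: np.ndarray  # (nx, ny) channel index at face site, else -1
    channel_occupant: np.ndarray  # (n_channels,) bound ligate id, else -1
    released: np.ndarray | None = None  # ids released this step (no same-step rebind)
    t: int = 0

    @property
    def n_bound(self) -> int:
        return int(np.sum(self.bound_to >= 0))


def init_state(config: WalkConfig, rng: np.random.Generator | None = None) -> WalkState:
    """Ligates uniform over off-face lattice sites; channels on the z=0 face."""
    rng = rng or np.random.default_rng(config.seed)
    ch = _channel_sites(config)
    if len(np.unique(ch[:, 0] * config.ny + ch[:, 1])) != len(ch):
        raise ValueError("channel site collision")
    cmap = np.full((config.nx, config.ny), -1, dtype=int)
    cmap[ch[:, 0], ch[:, 1]] = np.arange(len(ch))
    pos = np.column_stack(
        [
            rng.integers(0, config.nx, config.n_ligate),
            rng.integers(0, config.ny, config.n_ligate),
            rng.integers(1, config.nz, config.n_ligate),  # start off the channel face
        ]
    )
    return WalkState(
        positions=pos,
        channel_xy=ch,
        bound_to=np.full(config.n_ligate, -1, dtype=int),
        channel_map=cmap,
        channel_occupant=np.full(len(ch), -1, dtype=int),
        released=np.empty(0, dtype=int),
    )


_STEPS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=int
)


def step_walk(state: WalkState, config: WalkConfig, rng: np.random.Generator) -> WalkState:
    """Advance the state by one time step in place (also returns it).

    Phases: move all free ligates (independent, attraction-weighted toward
    channel sites), then resolve binding per unoccupied channel in
    ligate-index order, then attempt release for every bound ligate.
    Ligates released on the previous step move normally but ligates
    released in this step's phase 3 stay put and cannot rebind until the
    next step.
    """
    nx, ny, nz = config.nx, config.ny, config.nz
    pos, cmap = state.positions, state.channel_map
    dims = np.array([nx, ny, nz])

    # channel-site lookup on the face, for attraction weighting (the pull
    # acts on any channel position, occupied or not)
    is_channel = cmap >= 0

    # --- phase 1: move all free ligates (vectorized) ---------------------
    free_ids = np.where(state.bound_to < 0)[0]
    if len(free_ids):
        cand = pos[free_ids, None, :] + _STEPS[None, :, :]  # (m, 6, 3)
        valid = np.all(cand >= 0, axis=2) & np.all(cand < dims, axis=2)
        w = valid.astype(float)
        if config.attraction > 1.0:
            on_face = valid & (cand[:, :, 2] == 0)
            if on_face.any():
                boost = np.zeros_like(w)
                fx = np.where(on_face, cand[:, :, 0], 0)
                fy = np.where(on_face, cand[:, :, 1], 0)
                boost[on_face] = is_channel[fx[on_face], fy[on_face]]
                w = w * (1.0 + (config.attraction - 1.0) * boost)
        cw = np.cumsum(w, axis=1)
        u = rng.uniform(size=len(free_ids)) * cw[:, -1]
        choice = (u[:, None] >= cw).sum(axis=1)
        pos[free_ids] = cand[np.arange(len(free_ids)), choice]

    # --- phase 2: binding, per unoccupied channel, ligate-index order ----
    on_face_ids = free_ids[pos[free_ids, 2] == 0] if len(free_ids) else free_ids
    if len(on_face_ids):
        ch_here = cmap[pos[on_face_ids, 0], pos[on_face_ids, 1]]
        at_channel = ch_here >= 0
        for i, ci in zip(on_face_ids[at_channel], ch_here[at_channel]):
            if state.channel_occupant[ci] >= 0:
                continue
            if config.p_bind > 0 and rng.uniform() < config.p_bind:
                state.channel_occupant[ci] = i
                state.bound_to[i] = ci

    # --- phase 3: release (ligate stays at the site, free next step) -----
    bound_ids = np.where(state.bound_to >= 0)[0]
    newly_released = np.empty(0, dtype=int)
    if len(bound_ids) and config.p_unbind > 0:
        rel = bound_ids[rng.uniform(size=len(bound_ids)) < config.p_unbind]
        if len(rel):
            state.channel_occupant[state.bound_to[rel]] = -1
            state.bound_to[rel] = -1
            newly_released = rel
    state.released = newly_released

    state.t += 1
    return state


def run_walk(
    config: WalkConfig, seed: int | None = None
) -> tuple[np.ndarray, WalkState]:
    """One replicate: returns the bound-count trace (n_steps,) and final state."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    state = init_state(config, rng)
    trace = np.empty(config.n_steps, dtype=int)
    for t in range(config.n_steps):
        step_walk(state, config, rng)
        trace[t] = state.n_bound
    return trace, state


@dataclass
class KdEstimate:
    kd_nM: float
    window: tuple[int, int]
    bound_fraction_trace: np.ndarray
    infinite: bool = False
    stationary: bool = True
    replicate_sd: float | None = None


def estimate_kd(
    trace: np.ndarray, config: WalkConfig, window_frac: float = 0.4
) -> KdEstimate:
    """Kd (nM) from the equilibrated tail of a bound-count trace.

    Kd = [free ligate] x (free channels) / (bound channels), means taken
    over the last ``window_frac`` of the trace.  Zero bound channels in
    the window gives an infinite-Kd flag.  A stationarity check compares
    the two halves of the window (flagged when they differ by > 20%).
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    start = int(np.floor(n * (1.0 - window_frac)))
    window = trace[start:]
    mean_bound = window.mean()
    frac_trace = trace / max(config.n_channels, 1)
    if mean_bound == 0:
        return KdEstimate(np.inf, (start, n), frac_trace, infinite=True)
    half = len(window) // 2
    stationary = True
    if half >= 1:
        m1, m2 = window[:half].mean(), window[half:].mean()
        if m1 > 0 and abs(m2 - m1) / m1 > 0.2:
            stationary = False
    free_lig = config.n_ligate - mean_bound
    free_ch = config.n_channels - mean_bound
    kd = config.concentration_nM(free_lig) * free_ch / mean_bound
    return KdEstimate(float(kd), (start, n), frac_trace, stationary=stationary)


def _rep_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _mean_kd(config: WalkConfig, n_reps: int, seed: int) -> tuple[float, np.ndarray]:
    """Kd from replicate-averaged occupancy, plus the per-rep Kd values."""
    kds = np.empty(n_reps)
    bounds = np.empty(n_reps)
    for r, s in enumerate(_rep_seeds(seed, n_reps)):
        trace, _ = run_walk(config, seed=s)
        est = estimate_kd(trace, config)
        kds[r] = est.kd_nM
        start = est.window[0]
        bounds[r] = np.asarray(trace, float)[start:].mean()
    mb = bounds.mean()
    if mb == 0:
        return np.inf, kds
    kd = config.concentration_nM(config.n_ligate - mb) * (config.n_channels - mb) / mb
    return float(kd), kds


def calibrate_probabilities(
    target_kd_nM: float,
    grid: Sequence[tuple[float, float]],
    config: WalkConfig,
    n_reps: int = 20,
    tolerance: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Scan (p_bind, p_unbind) combinations for Kd near the target.

    Runs ``n_reps`` replicates per grid point, estimates Kd from pooled
    occupancy, and returns a table sorted by |Kd - target| with a
    ``calibrated`` flag for points within ``tolerance`` (relative).  All
    points infinite raises a calibration-failure error.
    """
    if not len(grid):
        raise ValueError("empty probability grid")
    rows = []
    for gi, (pb, pu) in enumerate(grid):
        cfg = _with_probs(config, pb, pu)
        kd, _ = _mean_kd(cfg, n_reps, seed + gi)
        rows.append(
            {
                "p_bind": pb,
                "p_unbind": pu,
                "kd_nM": kd,
                "abs_error_nM": abs(kd - target_kd_nM) if np.isfinite(kd) else np.inf,
                "infinite": not np.isfinite(kd),
            }
        )
    df = pd.DataFrame(rows).sort_values("abs_error_nM").reset_index(drop=True)
    df["calibrated"] = df["abs_error_nM"] <= tolerance * target_kd_nM
    if df["infinite"].all():
        raise RuntimeError("calibration failure: all grid points gave infinite Kd")
    return df


def _with_probs(config: WalkConfig, p_bind: float, p_unbind: float) -> WalkConfig:
    d = {k: getattr(config, k) for k in WalkConfig.__dataclass_fields__}
    d.update(p_bind=p_bind, p_unbind=p_unbind)
    return WalkConfig(**d)


def _with_arrangement(config: WalkConfig, arrangement: str) -> WalkConfig:
    d = {k: getattr(config, k) for k in WalkConfig.__dataclass_fields__}
    d.update(arrangement=arrangement)
    return WalkConfig(**d)


def compare_arrangements(
    config: WalkConfig, n_reps: int | None = None, seed: int = 0
) -> dict:
    """Paired Kd comparison, clustered vs. distributed channels.

    Replicates use common random seeds across the two arrangements; the
    difference is assessed with a one-sided Wilcoxon signed-rank test
    (alternative: clustered < distributed).
    """
    n_reps = n_reps or config.n_reps
    out = {}
    for arr in _ARRANGEMENTS:
        cfg = _with_arrangement(config, arr)
        kd_pool, kds = _mean_kd(cfg, n_reps, seed)
        out[arr] = {"kd_nM": kd_pool, "per_rep": kds}
    a = out["clustered"]["per_rep"]
    b = out["distributed"]["per_rep"]
    finite = np.isfinite(a) & np.isfinite(b)
    if finite.sum() >= 5 and np.any(a[finite] != b[finite]):
        stat, p = stats.wilcoxon(a[finite], b[finite], alternative="less")
    else:
        stat, p = np.nan, np.nan
    return {
        "clustered_kd_nM": out["clustered"]["kd_nM"],
        "distributed_kd_nM": out["distributed"]["kd_nM"],
        "clustered_per_rep": a,
        "distributed_per_rep": b,
        "wilcoxon_stat": float(stat) if np.isfinite(stat) else stat,
        "p_value_one_sided": float(p) if np.isfinite(p) else p,
        "n_reps": n_reps,
    }
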