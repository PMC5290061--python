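"""Corn root-system sub-model on the 76 × 100 cm soil profile.

Roots are represented as unconnected 1-cm³ segments, each belonging to one
of root nodes 1–7 (whorls).  Crop emergence is triggered by heat accumulation
above a 10 °C base plus a water-content condition at sowing depth.  After
emergence each developed node spawns 0–3 new segments per day inside
node-specific horizontal/vertical boundaries for the first 56 days; each
segment then gains mass linearly for 30 days.  Natural root senescence is
deliberately not modelled — the only losses are larval feeding and
feeding-induced pruning, recorded in per-node ledgers so that damage can be
scored against the pest-free twin run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import GRID_WIDTH, GRID_DEPTH, CENTER_X, wrap_x, clamp_y

N_NODES = 7

# Root-mass attractiveness bands (g/patch of individual segment mass).
# Larval instars preferentially forage on roots of their own size class;
# segments above the top edge are too old (woody) to attract any instar.
L1_BAND = (0.0, 0.00094)      # open: 0 < m < 0.00094
L2_BAND = (0.00095, 0.002)    # closed: 0.00095 <= m <= 0.002
L3_BAND = (0.002, 0.005)      # half-open: 0.002 < m <= 0.005


@dataclass
class RootParams:
    """Root growth parameters.

    Spatial/temporal placement values (``node_day``, ``hrrd``, ``vrrdf``) and
    the per-segment growth increment ``rg`` are calibration parameters of the
    root sub-model: defaults are chosen so nodes appear in shallow-to-deep
    order on a weekly cadence and total pest-free mass rises linearly to a
    few grams per 7.6 L by ~80 days after emergence (see docs/methods.md).
    """

    base_temp_c: float = 10.0          # baseline for heat accumulation and growth
    gdd_emergence: float = 43.0        # °C·day heat sum triggering emergence
    wc_emergence_pct: float = 30.0     # water content required at sowing depth
    growth_window_c: tuple[float, float] = (10.0, 30.0)  # ST_a gate for expansion
    expansion_days: int = 56           # new segments only this long after emergence
    segment_growth_days: int = 30      # each segment grows this many days
    rg: float = 0.0004                 # g mass gain per segment per day
    max_daily_segments: int = 3        # spawn count ~ uniform{0..3} per node-day
    node_day: tuple[int, ...] = (0, 7, 14, 21, 28, 35, 42)   # node appearance offsets
    hrrd: tuple[float, ...] = (3.0, 5.0, 8.0, 11.0, 14.0, 17.0, 20.0)  # horiz. sd, cm
    vrrdf: tuple[float, ...] = (1.5, 1.3, 1.1, 0.9, 0.7, 0.5, 0.35)    # cm depth per day of node age
    vertical_scatter_frac: float = 0.15  # sd of vertical scatter, fraction of anchor

    def validate(self) -> None:
        if len(self.node_day) != N_NODES or len(self.hrrd) != N_NODES \
                or len(self.vrrdf) != N_NODES:
            raise ValueError("node_day, hrrd and vrrdf must have 7 entries")
        if any(b <= a for a, b in zip(self.node_day, self.node_day[1:])):
            raise ValueError("node appearance days must be strictly increasing")
        if self.rg <= 0:
            raise ValueError("rg must be > 0")
        if self.expansion_days <= 0 or self.segment_growth_days <= 0:
            raise ValueError("durations must be > 0")


class RootState:
    """Mutable root-system state: emergence tracker, segments, loss ledgers."""

    def __init__(self, capacity: int = 2048):
        self.emerged = False
        self.emergence_day: int | None = None
        self.heat_accum = 0.0   # °C·day above base, accumulated hourly
        self.n = 0
        self._cap = capacity
        self.node = np.zeros(capacity, dtype=np.int64)
        self.birth_day = np.zeros(capacity, dtype=np.int64)
        self.x = np.zeros(capacity, dtype=np.int64)
        self.y = np.zeros(capacity, dtype=np.int64)
        self.mass = np.zeros(capacity, dtype=float)
        self.alive = np.zeros(capacity, dtype=bool)
        # per-node ledgers (index 0 == node 1), in grams
        self.grown = np.zeros(N_NODES)
        self.eaten = np.zeros(N_NODES)
        self.pruned = np.zeros(N_NODES)
        self._patch: dict[tuple[int, int], list[int]] = {}

    # -- emergence ---------------------------------------------------------

    def update_emergence_hour(self, temp_sowing_c: float, wc_pct: float,
                              params: RootParams, day: int) -> bool:
        """Advance the hourly heat sum; fire emergence when all gates open.

        Heat accumulates as max(0, T − base)/24 °C·day per hour from sowing.
        Emergence fires at the first hour where the accumulated sum has
        reached the threshold AND the instantaneous sowing-depth temperature
        exceeds the base AND water content exceeds the germination threshold.
        """
        if self.emerged:
            return False
        self.heat_accum += max(0.0, temp_sowing_c - params.base_temp_c) / 24.0
        if (self.heat_accum >= params.gdd_emergence
                and temp_sowing_c > params.base_temp_c
                and wc_pct > params.wc_emergence_pct):
            self.emerged = True
            self.emergence_day = day
            return True
        return False

    # -- segments ----------------------------------------------------------

    def _ensure_capacity(self, extra: int) -> None:
        if self.n + extra <= self._cap:
            return
        new_cap = max(self._cap * 2, self.n + extra)
        for name in ("node", "birth_day", "x", "y"):
            arr = getattr(self, name)
            grown = np.zeros(new_cap, dtype=arr.dtype)
            grown[:self.n] = arr[:self.n]
            setattr(self, name, grown)
        mass = np.zeros(new_cap)
        mass[:self.n] = self.mass[:self.n]
        self.mass = mass
        alive = np.zeros(new_cap, dtype=bool)
        alive[:self.n] = self.alive[:self.n]
        self.alive = alive
        self._cap = new_cap

    def add_segments(self, nodes, day: int, xs, ys) -> None:
        nodes = np.atleast_1d(nodes)
        xs = np.atleast_1d(xs)
        ys = np.atleast_1d(ys)
        k = nodes.size
        self._ensure_capacity(k)
        sl = slice(self.n, self.n + k)
        self.node[sl] = nodes
        self.birth_day[sl] = day
        self.x[sl] = xs
        self.y[sl] = ys
        self.mass[sl] = 0.0
        self.alive[sl] = True
        for i in range(self.n, self.n + k):
            self._patch.setdefault((int(self.x[i]), int(self.y[i])), []).append(i)
        self.n += k

    def segments_in_patch(self, x: int, y: int) -> np.ndarray:
        """Indices of alive segments resident in patch (x, y)."""
        idx = self._patch.get((int(x), int(y)))
        if not idx:
            return np.empty(0, dtype=np.int64)
        idx = np.asarray(idx, dtype=np.int64)
        return idx[self.alive[idx]]

    def kill_segment(self, i: int, cause: str) -> None:
        """Mark segment ``i`` dead, moving its remaining mass to a ledger."""
        if not self.alive[i]:
            return
        node0 = int(self.node[i]) - 1
        if cause == "eaten":
            self.eaten[node0] += self.mass[i]
        elif cause == "pruned":
            self.pruned[node0] += self.mass[i]
        else:
            raise ValueError(f"unknown death cause {cause!r}")
        self.mass[i] = 0.0
        self.alive[i] = False

    # -- aggregates --------------------------------------------------------

    def alive_mass_per_node(self) -> np.ndarray:
        out = np.zeros(N_NODES)
        sl = slice(0, self.n)
        np.add.at(out, self.node[sl][self.alive[sl]] - 1,
                  self.mass[sl][self.alive[sl]])
        return out

    def total_alive_mass(self) -> float:
        return float(self.mass[:self.n][self.alive[:self.n]].sum())

    def n_alive_segments(self) -> int:
        return int(self.alive[:self.n].sum())

    def closure_residual(self) -> float:
        """Mass-balance residual grown − (alive + eaten + pruned), in g."""
        alive = self.alive_mass_per_node()
        return float(np.abs(self.grown - (alive + self.eaten + self.pruned)).max()) \
            if self.n else float(np.abs(self.grown - (self.eaten + self.pruned)).max())

    def segment_count_grid(self) -> np.ndarray:
        """(76, 100) count of alive segments per patch (the Nrs field)."""
        out = np.zeros((GRID_WIDTH, GRID_DEPTH), dtype=np.int64)
        sl = slice(0, self.n)
        m = self.alive[sl]
        np.add.at(out, (self.x[sl][m], self.y[sl][m] - 1), 1)
        return out


# ---------------------------------------------------------------------------
# Daily root processes
# ---------------------------------------------------------------------------

def active_nodes(day: int, emergence_day: int, params: RootParams) -> list[int]:
    """Nodes (1..7) spawning segments on ``day``: appeared, within 56 days."""
    if day > emergence_day + params.expansion_days:
        return []
    return [n for n in range(1, N_NODES + 1)
            if day >= emergence_day + params.node_day[n - 1]]


def place_segment(node: int, age_of_node_days: int, params: RootParams,
                  rng: np.random.Generator) -> tuple[int, int]:
    """Random position for a new segment of ``node`` at the given node age.

    Horizontal: centre of the profile ± a normal draw with node-specific
    spread, wrapped at the edges.  Vertical: the anchor depth is the node's
    vertical distribution factor times its age in days (roots of a node
    reach deeper as the node ages), with proportional scatter, clamped to
    the 1..100 cm profile.
    """
    hx = CENTER_X + rng.normal(0.0, params.hrrd[node - 1])
    x = int(wrap_x(int(round(hx))))
    anchor = params.vrrdf[node - 1] * age_of_node_days
    scatter = params.vertical_scatter_frac * anchor
    y = int(clamp_y(int(round(anchor + (rng.normal(0.0, scatter) if scatter > 0 else 0.0)))))
    return x, y


def draw_daily_segments(day: int, emergence_day: int, avg_profile_temp: float,
                        params: RootParams, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the day's new segments (nodes, xs, ys) without mutating state.

    Per developed node, 0–3 segments appear (uniformly at random) provided
    the profile-average soil temperature lies strictly inside the growth
    window.  The draw is independent of pest state, so the same schedule is
    shared between the pest run and its pest-free twin.
    """
    lo, hi = params.growth_window_c
    nodes_out, xs_out, ys_out = [], [], []
    if not (lo < avg_profile_temp < hi):
        return (np.empty(0, dtype=int),) * 3
    for n in active_nodes(day, emergence_day, params):
        k = int(rng.integers(0, params.max_daily_segments + 1))
        age = day - (emergence_day + params.node_day[n - 1])
        for _ in range(k):
            x, y = place_segment(n, age, params, rng)
            nodes_out.append(n)
            xs_out.append(x)
            ys_out.append(y)
    return (np.asarray(nodes_out, dtype=int), np.asarray(xs_out, dtype=int),
            np.asarray(ys_out, dtype=int))


def spawn_daily_segments(state: RootState, day: int, avg_profile_temp: float,
                         params: RootParams, rng: np.random.Generator) -> int:
    """Draw and insert the day's new segments; returns the number created."""
    if not state.emerged:
        return 0
    nodes, xs, ys = draw_daily_segments(day, state.emergence_day,
                                        avg_profile_temp, params, rng)
    if nodes.size:
        state.add_segments(nodes, day, xs, ys)
    return int(nodes.size)


def grow_segments(state: RootState, day: int, params: RootParams,
                  reduction: float = 0.0,
                  fed_grid: np.ndarray | None = None) -> None:
    """Daily linear mass growth of alive segments aged 1..30 days.

    Segments on patches that experienced larval feeding grow at a reduced
    rate ``rg·(1 − reduction)`` — damaged roots lose uptake function.  The
    per-node cumulative-growth ledger is updated alongside.
    """
    if state.n == 0:
        return
    sl = slice(0, state.n)
    age = day - state.birth_day[sl]
    growing = state.alive[sl] & (age >= 1) & (age <= params.segment_growth_days)
    if not growing.any():
        return
    inc = np.zeros(state.n)
    inc[growing] = params.rg
    if fed_grid is not None and reduction > 0.0:
        fed = fed_grid[state.x[sl], state.y[sl] - 1] & growing
        inc[fed] *= max(0.0, 1.0 - reduction)
    state.mass[sl] += inc
    np.add.at(state.grown, state.node[sl] - 1, inc)


# ---------------------------------------------------------------------------
# Patch mass queries (foraging attractiveness)
# ---------------------------------------------------------------------------

def _band_bounds(instar: int) -> tuple[float, float, bool, bool]:
    """(lo, hi, lo_inclusive, hi_inclusive) for instar 1..3."""
    if instar == 1:
        return (*L1_BAND, False, False)
    if instar == 2:
        return (*L2_BAND, True, True)
    if instar == 3:
        return (*L3_BAND, False, True)
    raise ValueError(f"instar must be 1..3, got {instar}")


def _band_mask(mass: np.ndarray, instar: int) -> np.ndarray:
    lo, hi, lo_inc, hi_inc = _band_bounds(instar)
    m_lo = (mass >= lo) if lo_inc else (mass > lo)
    m_hi = (mass <= hi) if hi_inc else (mass < hi)
    return m_lo & m_hi


def patch_root_mass(state: RootState, x: int, y: int, instar: int) -> float:
    """Attractive root mass in one patch for the given instar's band.

    Individual alive-segment masses are filtered to the instar's size band
    and summed; segments above 0.005 g are woody and attract no instar.
    """
    idx = state.segments_in_patch(x, y)
    if idx.size == 0:
        return 0.0
    mass = state.mass[idx]
    return float(mass[_band_mask(mass, instar)].sum())


def band_mass_grids(state: RootState) -> np.ndarray:
    """(3, 76, 100) attractive mass per patch for instars 1..3."""
    out = np.zeros((3, GRID_WIDTH, GRID_DEPTH))
    if state.n == 0:
        return out
    sl = slice(0, state.n)
    alive = state.alive[sl]
    mass = state.mass[sl]
    xs = state.x[sl]
    ys = state.y[sl] - 1
    for b in range(3):
        m = alive & _band_mask(mass, b + 1)
        if m.any():
            np.add.at(out[b], (xs[m], ys[m]), mass[m])
    return out
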