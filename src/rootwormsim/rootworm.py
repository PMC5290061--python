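"""Western corn rootworm life cycle on the soil-profile grid.

Eggs laid the previous autumn overwinter in the top 30 cm of soil, hatch in
early summer, and the three larval instars feed on corn roots before
pupating; adults emerging from the soil end the simulated year (the species
is univoltine, so no reproduction occurs within a run).  Development of every
below-ground stage is a linear function of the local hourly soil temperature
above a stage-specific baseline, saturating at 30 °C (for eggs the rate
declines again above the optimum).  Mortality acts per stage: a normally
distributed overwinter egg loss, starvation-driven establishment failure for
first instars (a decreasing Hill curve over starvation hours), and
development-linked hazards for L2 and for L3+pupa.  Larvae move at a
soil-type-specific cadence, and only when local food is insufficient,
towards the best patch of their preferred root-size band within sensing
distance; feeding is shared equally within a patch when food limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GRID_WIDTH, GRID_DEPTH, wrap_x, clamp_y
from .roots import RootState, band_mass_grids

# stage codes
EGG, L1, L2, L3, PUPA, ADULT = range(6)
STAGE_NAMES = ("egg", "L1", "L2", "L3", "pupa", "adult")
LARVAL_STAGES = (L1, L2, L3)

SOIL_TYPES = ("sand", "sandy_loam", "silt_loam")


@dataclass
class PestParams:
    """Rootworm parameters.

    The egg-depth fractions, feeding rate ``frl1``, movement intervals,
    sensing distance and root-mass band edges are field/assay values; the
    stage developmental rates and baselines, mortalities and the Hill
    establishment curve are defaults reconstructed from the cited
    literature relationships (degree-day stage totals, life-table
    magnitudes, instar-doubling feeding rates) — non-canonical and
    config-overridable, see docs/methods.md.

    Developmental rates are relative development per hour per °C above the
    stage baseline, i.e. ``1 / (24 · DD)`` for a stage requiring DD
    degree-days.
    """

    # oviposition
    ed1: float = 21.0            # % of eggs in 0–10 cm
    ed2: float = 45.0            # % of eggs in 10–20 cm
    ed3: float = 34.0            # % of eggs in 20–30 cm
    no_till_top_exclusion_cm: int = 2
    hend: float = 10.0           # no-till horizontal normal spread (cm)
    # development
    bte: float = 11.0            # egg baseline °C (region-specific input)
    btl1: float = 10.5
    btl2: float = 10.5
    btl3: float = 10.5
    btp: float = 10.5
    de: float = 1.0 / (200.0 * 24.0)    # egg: ~200 DD above base
    dl1: float = 1.0 / (90.0 * 24.0)    # L1: ~90 DD
    dl2: float = 1.0 / (100.0 * 24.0)   # L2: ~100 DD
    dl3: float = 1.0 / (130.0 * 24.0)   # L3: ~130 DD
    dp: float = 1.0 / (150.0 * 24.0)    # pupa: ~150 DD
    t_opt: float = 30.0          # development saturates (eggs: peaks) here
    # survival
    me_mean: float = 0.55        # overwinter egg mortality fraction
    me_sd: float = 0.10
    ml1a: float = 0.95           # establishment plateau at zero starvation
    ml1b: float = 3.5            # Hill slope over starvation hours
    ml1c: float = 30.0           # starvation half-time (h)
    ml2_mean: float = 0.40       # L2 whole-stage mortality
    ml2_sd: float = 0.05
    ml3_mean: float = 0.35       # L3 + pupa combined whole-stage mortality
    ml3_sd: float = 0.05
    # movement
    mf_sand: int = 1             # move opportunity every h in sand
    mf_sandy_loam: int = 4
    mf_silt_loam: int = 6
    sensing_distance: int = 5    # patches (Chebyshev)
    l1m: float = 0.00094         # band edges, g/patch
    l2m: float = 0.002
    l3m: float = 0.005
    # feeding
    frl1: float = 0.000015       # g root / larva / h
    frl2: float = 0.000030
    frl3: float = 0.000060
    pru: float = 0.90            # pruning parameter (calibrated, see methods)

    def validate(self) -> None:
        if abs(self.ed1 + self.ed2 + self.ed3 - 100.0) > 1e-9:
            raise ValueError("egg depth fractions must sum to 100 %")
        if not (self.frl3 > self.frl2 > self.frl1 > 0):
            raise ValueError("feeding rates must increase with instar")
        for r in (self.de, self.dl1, self.dl2, self.dl3, self.dp):
            if r < 0:
                raise ValueError("developmental rates must be >= 0")

    def movement_interval(self, soil_type: str) -> int:
        try:
            return {"sand": self.mf_sand,
                    "sandy_loam": self.mf_sandy_loam,
                    "silt_loam": self.mf_silt_loam}[soil_type]
        except KeyError:
            raise ValueError(
                f"unknown soil type {soil_type!r}; expected one of {SOIL_TYPES}")

    def baseline(self, stage: int) -> float:
        return (self.bte, self.btl1, self.btl2, self.btl3, self.btp)[stage]

    def dev_rate(self, stage: int) -> float:
        return (self.de, self.dl1, self.dl2, self.dl3, self.dp)[stage]

    def feeding_rate(self, stage: int) -> float:
        if stage == L1:
            return self.frl1
        if stage == L2:
            return self.frl2
        if stage == L3:
            return self.frl3
        return 0.0


def moves_per_day(soil_type: str, params: PestParams | None = None) -> int:
    params = params or PestParams()
    return 24 // params.movement_interval(soil_type)


def max_daily_displacement_cm(soil_type: str,
                              params: PestParams | None = None) -> float:
    """Maximum straight-line daily travel: all moves diagonal on the 1-cm grid."""
    return round(moves_per_day(soil_type, params) * np.sqrt(2.0), 1)


class Population:
    """Struct-of-arrays container for the rootworm individuals of one run."""

    def __init__(self, n: int):
        self.n = n
        self.stage = np.full(n, EGG, dtype=np.int64)
        self.dev = np.zeros(n)                 # relative development in [0, 1)
        self.x = np.zeros(n, dtype=np.int64)
        self.y = np.zeros(n, dtype=np.int64)
        self.starv_hours = np.zeros(n, dtype=np.int64)   # L1 starvation clock
        self.estab_u = np.full(n, np.nan)      # establishment threshold, per episode
        self.alive = np.ones(n, dtype=bool)

    def count(self, stage: int) -> int:
        return int(np.count_nonzero(self.alive & (self.stage == stage)))

    def larvae_indices(self) -> np.ndarray:
        return np.flatnonzero(self.alive & (self.stage >= L1) & (self.stage <= L3))

    def stage_counts(self) -> dict[str, int]:
        return {STAGE_NAMES[s]: self.count(s) for s in range(6)}


# ---------------------------------------------------------------------------
# Oviposition (previous autumn) and overwinter mortality
# ---------------------------------------------------------------------------

def place_eggs(ne: int, tillage: bool, params: PestParams,
               rng: np.random.Generator) -> Population:
    """Place the autumn egg census in the soil profile.

    Depth: 21/45/34 % in the 0–10 / 10–20 / 20–30 cm bands (uniform within
    a band); under no-till the top 2 cm are additionally excluded.
    Horizontal: uniform across the profile under tillage; under no-till a
    normal distribution centred on the furrow (the profile edge) with spread
    ``hend``, wrapped at the edges.
    """
    if ne < 0:
        raise ValueError("egg count must be >= 0")
    params.validate()
    pop = Population(ne)
    if ne == 0:
        return pop
    fracs = np.array([params.ed1, params.ed2, params.ed3]) / 100.0
    band = rng.choice(3, size=ne, p=fracs)
    top_min = params.no_till_top_exclusion_cm + 1 if not tillage else 1
    lo = np.array([top_min, 11, 21])
    hi = np.array([10, 20, 30])
    u = rng.random(ne)
    pop.y = (lo[band] + np.floor(u * (hi[band] - lo[band] + 1))).astype(np.int64)
    if tillage:
        pop.x = rng.integers(0, GRID_WIDTH, size=ne)
    else:
        furrow = rng.normal(0.0, params.hend, size=ne)
        pop.x = wrap_x(np.round(furrow).astype(np.int64))
    return pop


def winter_egg_mortality(pop: Population, params: PestParams,
                         rng: np.random.Generator) -> float:
    """Kill a normally distributed fraction of eggs; returns the fraction.

    One mortality fraction is drawn per run from N(me_mean, me_sd), truncated
    to [0, 1]; that fraction of eggs is killed uniformly at random (this also
    absorbs eggs staying dormant beyond one winter).
    """
    frac = float(np.clip(rng.normal(params.me_mean, params.me_sd), 0.0, 1.0))
    eggs = np.flatnonzero(pop.alive & (pop.stage == EGG))
    n_kill = int(round(frac * eggs.size))
    if n_kill > 0:
        pop.alive[rng.choice(eggs, size=n_kill, replace=False)] = False
    return frac


# ---------------------------------------------------------------------------
# Development
# ---------------------------------------------------------------------------

def development_increment(stage: np.ndarray, temp: np.ndarray,
                          params: PestParams) -> np.ndarray:
    """Hourly relative-development increment for each individual.

    Non-egg stages: rate · max(0, min(T, 30) − baseline).  Eggs rise
    linearly to the 30 °C optimum and then decline with the mirrored slope,
    floored at zero.
    """
    base = np.array([params.baseline(s) for s in range(5)])[stage]
    rate = np.array([params.dev_rate(s) for s in range(5)])[stage]
    t_eff = np.minimum(temp, params.t_opt)
    inc = rate * np.maximum(0.0, t_eff - base)
    egg = stage == EGG
    if egg.any():
        # mirrored decline above the optimum: effective T = 2·T_opt − T
        t_mirror = np.where(temp[egg] <= params.t_opt, temp[egg],
                            2.0 * params.t_opt - temp[egg])
        inc[egg] = rate[egg] * np.maximum(0.0, t_mirror - base[egg])
    return inc


def step_development(pop: Population, temp_by_depth: np.ndarray,
                     params: PestParams,
                     starv_scale: np.ndarray | None = None) -> np.ndarray:
    """Advance development one hour; returns the per-individual increment.

    ``starv_scale`` (aligned with the population) multiplies larval
    increments by min(1, Starv_i): underfed larvae develop proportionally
    slower.  Stage transitions fire at dev ≥ 1 with carry-over of the
    excess; the starvation episode does not cross a moult.
    """
    act = pop.alive & (pop.stage < ADULT)
    inc = np.zeros(pop.n)
    if not act.any():
        return inc
    idx = np.flatnonzero(act)
    temps = temp_by_depth[pop.y[idx] - 1]
    di = development_increment(pop.stage[idx], temps, params)
    if starv_scale is not None:
        larval = (pop.stage[idx] >= L1) & (pop.stage[idx] <= L3)
        di[larval] *= np.minimum(1.0, starv_scale[idx][larval])
    pop.dev[idx] += di
    inc[idx] = di
    trans = idx[pop.dev[idx] >= 1.0]
    if trans.size:
        pop.dev[trans] -= 1.0
        pop.stage[trans] += 1
        pop.starv_hours[trans] = 0
        pop.estab_u[trans] = np.nan
    return inc


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def establishment_probability(starv_hours, params: PestParams):
    """Decreasing 3-parameter Hill curve of L1 establishment success.

    ``Estab(h) = ml1a · ml1c^ml1b / (ml1c^ml1b + h^ml1b)``: plateau ``ml1a``
    at zero starvation, half the plateau at ``ml1c`` hours, → 0 as h → ∞.
    First-instar mortality has no time component of its own — death occurs
    purely through failure to establish on a root.
    """
    h = np.asarray(starv_hours, dtype=float)
    chb = params.ml1c ** params.ml1b
    return params.ml1a * chb / (chb + np.power(h, params.ml1b))


def l1_establishment_check(pop: Population, params: PestParams) -> int:
    """Kill starving L1s whose establishment curve fell below their threshold.

    Each starvation episode draws one uniform threshold per larva (stored in
    ``estab_u``); the larva dies at the first hour where Estab(starv_hours)
    drops below it.  Feeding ends the episode and clears the threshold.
    """
    starving = np.flatnonzero(pop.alive & (pop.stage == L1)
                              & (pop.starv_hours > 0))
    if starving.size == 0:
        return 0
    prob = establishment_probability(pop.starv_hours[starving], params)
    dies = prob < pop.estab_u[starving]
    pop.alive[starving[dies]] = False
    return int(dies.sum())


def stage_hazard_probability(ml_stage: float, dev_increment) -> np.ndarray:
    """Per-step death probability tied to development, not time.

    Chosen so cumulative survival over a full stage (dev 0→1) equals
    1 − ml_stage however the stage is partitioned into steps:
    ``p = 1 − (1 − ml)^Δdev``.
    """
    return 1.0 - np.power(1.0 - ml_stage, np.asarray(dev_increment, dtype=float))


def apply_stage_hazards(pop: Population, dev_inc: np.ndarray, ml2: float,
                        ml3: float, rng: np.random.Generator) -> int:
    """Development-linked mortality for L2 and for L3+pupa (shared budget).

    L3 and pupa draw from one combined whole-period mortality ``ml3``; the
    per-step exponent is halved so survival over both stages multiplies to
    1 − ml3.
    """
    killed = 0
    for stages, ml, scale in (((L2,), ml2, 1.0), ((L3, PUPA), ml3, 0.5)):
        sel = np.flatnonzero(pop.alive & np.isin(pop.stage, stages)
                             & (dev_inc > 0))
        if sel.size == 0:
            continue
        p = stage_hazard_probability(ml, dev_inc[sel] * scale)
        dies = rng.random(sel.size) < p
        pop.alive[sel[dies]] = False
        killed += int(dies.sum())
    return killed


# ---------------------------------------------------------------------------
# Movement
# ---------------------------------------------------------------------------

def starvation_index(pop: Population, root_state: RootState,
                     seg_count_grid: np.ndarray | None = None) -> np.ndarray:
    """Starv_i = Nrs / Nl for each alive larva's patch (∞-like cap at Nrs).

    The local food-sufficiency index: the ratio of alive root segments to
    larvae in the patch.  Values < 1 trigger reduced feeding, starvation and
    foraging movement.
    """
    out = np.zeros(pop.n)
    larvae = pop.larvae_indices()
    if larvae.size == 0:
        return out
    if seg_count_grid is None:
        seg_count_grid = root_state.segment_count_grid()
    nl = np.zeros((GRID_WIDTH, GRID_DEPTH), dtype=np.int64)
    np.add.at(nl, (pop.x[larvae], pop.y[larvae] - 1), 1)
    xs, ys = pop.x[larvae], pop.y[larvae] - 1
    out[larvae] = seg_count_grid[xs, ys] / nl[xs, ys]
    return out


def movement_step(pop: Population, i: int, band_grids: np.ndarray,
                  params: PestParams, rng: np.random.Generator) -> None:
    """Move larva ``i`` one patch: directed to food if sensed, else random.

    The larva surveys its instar's root-mass band within Chebyshev distance
    ``sensing_distance`` (horizontal wrap, vertical clamp) and steps one
    patch (diagonals allowed) towards the richest patch, ties broken
    uniformly; with no in-band root in range it takes a uniform step to one
    of its 8 neighbours.
    """
    sd = params.sensing_distance
    instar = int(pop.stage[i]) - L1
    x0, y0 = int(pop.x[i]), int(pop.y[i])
    xs = wrap_x(np.arange(x0 - sd, x0 + sd + 1))
    y_lo = max(1, y0 - sd)
    y_hi = min(GRID_DEPTH, y0 + sd)
    window = band_grids[instar][np.ix_(xs, np.arange(y_lo - 1, y_hi))]
    best = window.max()
    if best > 0.0:
        cand = np.argwhere(window == best)
        dx_off, dy_off = cand[rng.integers(cand.shape[0])]
        dx = int(dx_off) - sd
        dy = (y_lo + int(dy_off)) - y0
        step_x = int(np.sign(dx))
        step_y = int(np.sign(dy))
        if step_x == 0 and step_y == 0:
            return  # best patch is where it stands
    else:
        # random walk: uniform over the 8 neighbours
        while True:
            step_x = int(rng.integers(-1, 2))
            step_y = int(rng.integers(-1, 2))
            if step_x or step_y:
                break
    pop.x[i] = int(wrap_x(x0 + step_x))
    pop.y[i] = int(clamp_y(y0 + step_y))


def move_larvae(pop: Population, root_state: RootState, hour: int,
                soil_type: str, params: PestParams,
                rng: np.random.Generator,
                starv: np.ndarray | None = None,
                band_grids: np.ndarray | None = None) -> int:
    """Hourly movement pass: starving larvae move at the soil-type cadence."""
    interval = params.movement_interval(soil_type)
    if hour % interval != 0:
        return 0
    larvae = pop.larvae_indices()
    if larvae.size == 0:
        return 0
    if starv is None:
        starv = starvation_index(pop, root_state)
    movers = larvae[starv[larvae] < 1.0]
    if movers.size == 0:
        return 0
    if band_grids is None:
        band_grids = band_mass_grids(root_state)
    for i in movers:
        movement_step(pop, int(i), band_grids, params, rng)
    return int(movers.size)


# ---------------------------------------------------------------------------
# Feeding and pruning
# ---------------------------------------------------------------------------

def feed_patch(root_state: RootState, x: int, y: int,
               larvae_idx: np.ndarray, pop: Population, params: PestParams,
               dt_hours: float = 1.0) -> tuple[float, int]:
    """One hour of feeding by the larvae standing in patch (x, y).

    If the alive root mass covers the summed demand, every larva eats its
    full stage ration and its starvation clock resets; otherwise the
    available mass is shared equally and every larva in the patch accrues
    one hour of starvation.  Segments are consumed smallest-first so fully
    eaten segments die individually.  Returns (mass removed, segments
    killed).
    """
    rates = np.array([params.feeding_rate(int(s)) for s in pop.stage[larvae_idx]])
    demand = float(rates.sum() * dt_hours)
    seg_idx = root_state.segments_in_patch(x, y)
    avail = float(root_state.mass[seg_idx].sum()) if seg_idx.size else 0.0
    newly_starving = None
    if demand <= 0.0:
        return 0.0, 0
    if avail >= demand and seg_idx.size:
        removed_total = demand
        pop.starv_hours[larvae_idx] = 0
        pop.estab_u[larvae_idx] = np.nan
    else:
        removed_total = avail
        newly_starving = larvae_idx[(pop.starv_hours[larvae_idx] == 0)
                                    & (pop.stage[larvae_idx] == L1)]
        pop.starv_hours[larvae_idx] += 1
    ndr = 0
    if removed_total > 0.0 and seg_idx.size:
        order = seg_idx[np.argsort(root_state.mass[seg_idx], kind="stable")]
        remaining = removed_total
        for s in order:
            if remaining <= 0.0:
                break
            m = root_state.mass[s]
            bite = min(m, remaining)
            node0 = int(root_state.node[s]) - 1
            root_state.mass[s] -= bite
            root_state.eaten[node0] += bite
            remaining -= bite
            if root_state.mass[s] <= 1e-15:
                root_state.mass[s] = 0.0
                root_state.alive[s] = False
                ndr += 1
    if newly_starving is not None and newly_starving.size:
        # threshold for the new starvation episode is drawn by the caller
        pop.estab_u[newly_starving] = -1.0  # sentinel: needs a draw
    return removed_total, ndr


def feed_all_patches(pop: Population, root_state: RootState,
                     params: PestParams, rng: np.random.Generator,
                     fed_grid: np.ndarray) -> tuple[float, int]:
    """Hourly feeding pass over every patch holding larvae.

    Marks patches where feeding removed mass in ``fed_grid`` (used for the
    next day's growth reduction).  Returns (total mass removed, Ndr
    contribution of the hour).
    """
    larvae = pop.larvae_indices()
    removed_total, ndr_total = 0.0, 0
    if larvae.size == 0:
        return removed_total, ndr_total
    keys = pop.x[larvae] * (GRID_DEPTH + 1) + pop.y[larvae]
    order = np.argsort(keys, kind="stable")
    larvae = larvae[order]
    keys = keys[order]
    bounds = np.flatnonzero(np.r_[True, np.diff(keys) != 0, True])
    for a, b in zip(bounds[:-1], bounds[1:]):
        group = larvae[a:b]
        x, y = int(pop.x[group[0]]), int(pop.y[group[0]])
        removed, ndr = feed_patch(root_state, x, y, group, pop, params)
        if removed > 0.0:
            fed_grid[x, y - 1] = True
        removed_total += removed
        ndr_total += ndr
    need_u = np.flatnonzero(pop.estab_u == -1.0)
    if need_u.size:
        pop.estab_u[need_u] = rng.random(need_u.size)
    return removed_total, ndr_total


def apply_pruning(root_state: RootState, ndr_yesterday: int,
                  params: PestParams, rng: np.random.Generator) -> int:
    """Daily randomised pruning of surviving segments after feeding damage.

    Each alive segment dies with probability
    ``min(1, pru · Ndr / Nrs_total)`` where Ndr is yesterday's count of
    fully eaten segments and Nrs_total the current alive-segment count;
    killed mass enters the per-node pruned ledger.  Returns segments killed.
    """
    if ndr_yesterday <= 0 or params.pru <= 0.0:
        return 0
    alive_idx = np.flatnonzero(root_state.alive[:root_state.n])
    nrs = alive_idx.size
    if nrs == 0:
        return 0
    p = min(1.0, params.pru * ndr_yesterday / nrs)
    dies = alive_idx[rng.random(nrs) < p]
    for s in dies:
        root_state.kill_segment(int(s), "pruned")
    return int(dies.size)
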