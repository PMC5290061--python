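"""Simulation orchestration: scheduling, twin runs, replicates.

One replicate runs the calendar year from Julian day 1 to the damage
assessment day.  Hourly processes: egg/larval/pupal development, mortality
checks, foraging movement, feeding.  Daily processes: root-segment
spawning, root mass growth, pruning, ledgers.  The root sub-model runs
twice in parallel with a shared random stream — once pest-free, once with
the pest — so damage can be scored against identical pest-free growth.
Replicates are independent seeded runs whose outputs are averaged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .climate import (ClimateConfig, MoistureSeries, TemperatureField,
                      HOURS_PER_DAY, day_hour_range, generate_synthetic_climate,
                      load_moisture_series, load_temperature_profile)
from .damage import NodeLossLedger, compute_nis
from .grid import GRID_WIDTH, GRID_DEPTH, SOWING_DEPTH_CM
from .roots import (RootParams, RootState, draw_daily_segments, grow_segments)
from .rootworm import (ADULT, L1, PestParams, SOIL_TYPES,
                       apply_pruning, apply_stage_hazards, feed_all_patches,
                       l1_establishment_check, move_larvae, place_eggs,
                       starvation_index, step_development,
                       winter_egg_mortality)


@dataclass
class RunConfig:
    """Scalar run configuration plus all parameter blocks."""

    planting_day: int = 125          # Julian day of sowing
    days_to_assessment: int = 80     # damage assessed this many days later
    soil_type: str = "sand"
    tillage: bool = True
    eggs: int = 137                  # autumn egg census per 7.6 L profile
    n_replicates: int = 40
    seed: int = 1
    temperature_path: str | None = None   # hourly profile CSV; None → synthetic
    moisture_path: str | None = None
    climate: ClimateConfig = dc_field(default_factory=ClimateConfig)
    roots: RootParams = dc_field(default_factory=RootParams)
    pest: PestParams = dc_field(default_factory=PestParams)

    @property
    def assessment_day(self) -> int:
        return self.planting_day + self.days_to_assessment

    def validate(self) -> None:
        if self.soil_type not in SOIL_TYPES:
            raise ValueError(
                f"unknown soil type {self.soil_type!r}; expected one of {SOIL_TYPES}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.planting_day < 1 or self.days_to_assessment < 1:
            raise ValueError("planting day and days-to-assessment must be >= 1")
        if self.eggs < 0:
            raise ValueError("egg count must be >= 0")
        self.roots.validate()
        self.pest.validate()
        self.climate.validate()

    # -- YAML round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        climate = ClimateConfig(**d.pop("climate", {}))
        roots_d = dict(d.pop("roots", {}))
        for key in ("node_day", "hrrd", "vrrdf", "growth_window_c"):
            if key in roots_d and isinstance(roots_d[key], list):
                roots_d[key] = tuple(roots_d[key])
        roots = RootParams(**roots_d)
        pest = PestParams(**d.pop("pest", {}))
        return cls(climate=climate, roots=roots, pest=pest, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ReplicateResult:
    seed: object
    nis: float
    total_node_equivalents_lost: float
    yield_loss_pct: float
    yield_loss_sd_pct: float
    first_larva_day: int | None
    first_adult_day: int | None
    emergence_day: int | None
    winter_mortality_frac: float
    pruned_fraction: float          # seasonal root-mass reduction caused by
                                    # pruning, excluding direct feeding:
                                    # (twin mass − pest mass − eaten) / twin mass
    ledger: NodeLossLedger
    twin_grown_g: np.ndarray
    pest_grown_g: np.ndarray
    eaten_g: np.ndarray
    pruned_g: np.ndarray
    daily: pd.DataFrame
    max_closure_residual_g: float
    root_state: RootState | None = None   # final pest-run root system
    twin_state: RootState | None = None   # final pest-free twin


@dataclass
class SimulationOutput:
    """Replicate results plus their aggregate (means, SDs, 95 % CIs)."""

    config: RunConfig
    replicates: list[ReplicateResult]
    aggregate: dict

    def summary_dict(self) -> dict:
        return {
            "config": {"planting_day": self.config.planting_day,
                       "days_to_assessment": self.config.days_to_assessment,
                       "soil_type": self.config.soil_type,
                       "tillage": self.config.tillage,
                       "eggs": self.config.eggs,
                       "n_replicates": len(self.replicates),
                       "seed": self.config.seed},
            "aggregate": self.aggregate,
            "replicates": [{"nis": r.nis,
                            "yield_loss_pct": r.yield_loss_pct,
                            "first_larva_day": r.first_larva_day,
                            "first_adult_day": r.first_adult_day,
                            "pruned_fraction": r.pruned_fraction}
                           for r in self.replicates],
        }


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))


def _get_climate(config: RunConfig) -> tuple[TemperatureField, MoistureSeries]:
    if config.temperature_path is not None:
        temp = load_temperature_profile(config.temperature_path)
        if config.moisture_path is None:
            raise ValueError("moisture_path required with temperature_path")
        wc = load_moisture_series(config.moisture_path)
        return temp, wc
    cfg = dataclasses.replace(config.climate,
                              moisture_start_day=config.planting_day)
    return generate_synthetic_climate(cfg)


def run_simulation(config: RunConfig, seed: object,
                   climate: tuple[TemperatureField, MoistureSeries] | None = None
                   ) -> ReplicateResult:
    """Run one replicate; ``seed`` feeds a SeedSequence (int or tuple).

    Two independent streams are derived: one for root placement (shared by
    the pest run and its pest-free twin, which therefore grow identical
    root systems) and one for all pest stochasticity.
    """
    config.validate()
    temp, wc = climate if climate is not None else _get_climate(config)
    assessment_day = config.assessment_day
    if temp.hours < assessment_day * HOURS_PER_DAY:
        raise ValueError(
            f"climate horizon ({temp.hours} h) shorter than the simulation "
            f"horizon ({assessment_day * HOURS_PER_DAY} h)")

    ss = np.random.SeedSequence(seed)
    root_ss, pest_ss = ss.spawn(2)
    root_rng = np.random.default_rng(root_ss)
    pest_rng = np.random.default_rng(pest_ss)

    pest_p, root_p = config.pest, config.roots
    pop = place_eggs(config.eggs, config.tillage, pest_p, pest_rng)
    winter_frac = winter_egg_mortality(pop, pest_p, pest_rng)
    ml2_run = _truncated_normal(pest_rng, pest_p.ml2_mean, pest_p.ml2_sd)
    ml3_run = _truncated_normal(pest_rng, pest_p.ml3_mean, pest_p.ml3_sd)

    pest_roots = RootState()
    twin_roots = RootState()
    sowing_hour = (config.planting_day - 1) * HOURS_PER_DAY
    temp_sowing = temp.depth_series(SOWING_DEPTH_CM)
    reduction = min(1.0, pest_p.pru)

    fed_grid_yday = np.zeros((GRID_WIDTH, GRID_DEPTH), dtype=bool)
    ndr_yday = 0
    first_larva_day: int | None = None
    first_adult_day: int | None = None
    rows = []
    max_residual = 0.0

    for day in range(1, assessment_day + 1):
        # ---- daily root processes: spawn -> grow -> prune ----------------
        if pest_roots.emerged:
            avg_t = temp.daily_mean_profile_temperature(day)
            nodes, xs, ys = draw_daily_segments(
                day, pest_roots.emergence_day, avg_t, root_p, root_rng)
            if nodes.size:
                pest_roots.add_segments(nodes, day, xs, ys)
                twin_roots.add_segments(nodes, day, xs, ys)
            grow_segments(twin_roots, day, root_p)
            grow_segments(pest_roots, day, root_p, reduction=reduction,
                          fed_grid=fed_grid_yday)
            apply_pruning(pest_roots, ndr_yday, pest_p, pest_rng)

        fed_grid_today = np.zeros((GRID_WIDTH, GRID_DEPTH), dtype=bool)
        ndr_today = 0

        # ---- hourly loop: development -> mortality -> movement -> feeding
        h0, h1 = day_hour_range(day)
        for h in range(h0, h1):
            if (not pest_roots.emerged and h >= sowing_hour
                    and h >= wc.start_hour):
                fired = pest_roots.update_emergence_hour(
                    float(temp_sowing[h]), wc.at_hour(h), root_p, day)
                if fired:
                    twin_roots.emerged = True
                    twin_roots.emergence_day = day
                    twin_roots.heat_accum = pest_roots.heat_accum
            if not np.any(pop.alive & (pop.stage < ADULT)):
                continue
            seg_grid = pest_roots.segment_count_grid()
            starv = starvation_index(pop, pest_roots, seg_grid)
            dev_inc = step_development(pop, temp.values[h], pest_p,
                                       starv_scale=starv)
            if first_larva_day is None and np.any(
                    pop.alive & (pop.stage >= L1)):
                first_larva_day = day
            if first_adult_day is None and np.any(
                    pop.alive & (pop.stage == ADULT)):
                first_adult_day = day
            l1_establishment_check(pop, pest_p)
            apply_stage_hazards(pop, dev_inc, ml2_run, ml3_run, pest_rng)
            move_larvae(pop, pest_roots, h, config.soil_type, pest_p,
                        pest_rng)
            _, ndr = feed_all_patches(pop, pest_roots, pest_p, pest_rng,
                                      fed_grid_today)
            ndr_today += ndr

        fed_grid_yday = fed_grid_today
        ndr_yday = ndr_today
        residual = pest_roots.closure_residual()
        max_residual = max(max_residual, residual)
        counts = pop.stage_counts()
        rows.append({"day": day,
                     "eggs": counts["egg"], "L1": counts["L1"],
                     "L2": counts["L2"], "L3": counts["L3"],
                     "pupae": counts["pupa"], "adults_cum": counts["adult"],
                     "root_alive_pest_g": pest_roots.total_alive_mass(),
                     "root_alive_twin_g": twin_roots.total_alive_mass(),
                     "closure_residual_g": residual})

    lost = pest_roots.eaten + pest_roots.pruned
    ledger = NodeLossLedger(grown_g=twin_roots.grown.copy(), lost_g=lost,
                            assessment_day=assessment_day)
    twin_total = float(twin_roots.grown.sum())
    if twin_total > 0:
        dmg = compute_nis(ledger)
        nis, total_pct = dmg.nis, dmg.total_node_equivalents_lost
        yl, yl_sd = dmg.yield_loss_pct, dmg.yield_loss_sd_pct
        eaten_total = float(pest_roots.eaten.sum())
        pest_alive_total = pest_roots.total_alive_mass()
        pruned_fraction = (twin_total - pest_alive_total - eaten_total) / twin_total
    else:
        # crop never emerged: no roots, no damage to score
        nis, total_pct, yl, yl_sd, pruned_fraction = 0.0, 0.0, 0.0, 0.0, 0.0

    return ReplicateResult(
        seed=seed, nis=nis, total_node_equivalents_lost=total_pct,
        yield_loss_pct=yl, yield_loss_sd_pct=yl_sd,
        first_larva_day=first_larva_day, first_adult_day=first_adult_day,
        emergence_day=pest_roots.emergence_day,
        winter_mortality_frac=winter_frac,
        pruned_fraction=pruned_fraction, ledger=ledger,
        twin_grown_g=twin_roots.grown.copy(),
        pest_grown_g=pest_roots.grown.copy(),
        eaten_g=pest_roots.eaten.copy(), pruned_g=pest_roots.pruned.copy(),
        daily=pd.DataFrame(rows), max_closure_residual_g=max_residual,
        root_state=pest_roots, twin_state=twin_roots)


def replicate_seed(master_seed: int, replicate: int) -> tuple[int, int]:
    """Documented replicate seeding scheme: SeedSequence((master, index))."""
    return (master_seed, replicate)


def run_replicates(config: RunConfig,
                   n_replicates: int | None = None) -> SimulationOutput:
    """Run ``n_replicates`` independent replicates and aggregate them."""
    config.validate()
    n = n_replicates if n_replicates is not None else config.n_replicates
    climate = _get_climate(config)
    reps = [run_simulation(config, replicate_seed(config.seed, r),
                           climate=climate)
            for r in range(n)]

    def _agg(values):
        arr = np.array([v for v in values if v is not None], dtype=float)
        if arr.size == 0:
            return {"mean": None, "sd": None, "ci95_half_width": None}
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return {"mean": float(arr.mean()), "sd": sd,
                "ci95_half_width": 1.96 * sd / np.sqrt(arr.size)}

    aggregate = {
        "n_replicates": n,
        "nis": _agg([r.nis for r in reps]),
        "yield_loss_pct": _agg([r.yield_loss_pct for r in reps]),
        "first_larva_day": _agg([r.first_larva_day for r in reps]),
        "first_adult_day": _agg([r.first_adult_day for r in reps]),
        "pruned_fraction": _agg([r.pruned_fraction for r in reps]),
    }
    return SimulationOutput(config=config, replicates=reps, aggregate=aggregate)
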