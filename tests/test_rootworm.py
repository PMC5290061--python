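"""Pest life cycle: oviposition, development, survival, movement, feeding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rootwormsim.roots import RootState
from rootwormsim.rootworm import (EGG, L1, L2, L3, PUPA, ADULT, PestParams,
                                  Population, apply_pruning,
                                  apply_stage_hazards,
                                  development_increment,
                                  establishment_probability,
                                  feed_all_patches, feed_patch,
                                  l1_establishment_check,
                                  max_daily_displacement_cm, move_larvae,
                                  moves_per_day, place_eggs,
                                  stage_hazard_probability,
                                  starvation_index, step_development,
                                  winter_egg_mortality)


def larvae_at(positions, stage=L1):
    pop = Population(len(positions))
    pop.stage[:] = stage
    for i, (x, y) in enumerate(positions):
        pop.x[i], pop.y[i] = x, y
    return pop


def roots_at(positions, mass=0.0005):
    state = RootState()
    n = len(positions)
    state.add_segments(np.ones(n, dtype=int), 1,
                       np.array([p[0] for p in positions]),
                       np.array([p[1] for p in positions]))
    state.mass[:n] = mass
    state.grown[0] = state.mass[:n].sum()  # keep the mass ledger closed
    return state


class TestOviposition:
    def test_zero_eggs_empty_population(self, pest_params, rng):
        pop = place_eggs(0, True, pest_params, rng)
        assert pop.n == 0

    def test_negative_count_rejected(self, pest_params, rng):
        with pytest.raises(ValueError):
            place_eggs(-1, True, pest_params, rng)

    def test_tillage_depth_bands_match_field_fractions(self, pest_params, rng):
        pop = place_eggs(100_000, True, pest_params, rng)
        frac1 = np.mean(pop.y <= 10) * 100
        frac2 = np.mean((pop.y > 10) & (pop.y <= 20)) * 100
        frac3 = np.mean((pop.y > 20) & (pop.y <= 30)) * 100
        assert frac1 == pytest.approx(21.0, abs=0.5)
        assert frac2 == pytest.approx(45.0, abs=0.5)
        assert frac3 == pytest.approx(34.0, abs=0.5)
        assert pop.y.max() <= 30

    def test_tillage_horizontal_uniform(self, pest_params, rng):
        pop = place_eggs(100_000, True, pest_params, rng)
        counts = np.bincount(pop.x, minlength=76)
        assert counts.min() > 0.7 * counts.mean()

    def test_no_till_excludes_top_two_cm(self, pest_params, rng):
        pop = place_eggs(100_000, False, pest_params, rng)
        assert np.count_nonzero(pop.y <= 2) == 0
        assert pop.y.min() == 3

    def test_no_till_concentrated_at_furrow_with_wrap(self, pest_params, rng):
        pop = place_eggs(50_000, False, pest_params, rng)
        # wrapped distance from the furrow at x = 0
        dist = np.minimum(pop.x, 76 - pop.x)
        assert np.mean(dist <= pest_params.hend) > 0.6
        assert pop.x.min() >= 0 and pop.x.max() <= 75


class TestDevelopment:
    def test_zero_increment_at_stage_baseline(self, pest_params):
        for stage in range(5):
            base = pest_params.baseline(stage)
            inc = development_increment(np.array([stage]),
                                        np.array([base]), pest_params)
            assert inc[0] == 0.0

    def test_non_egg_rate_saturates_above_optimum(self, pest_params):
        for stage in (L1, L2, L3, PUPA):
            at30 = development_increment(np.array([stage]), np.array([30.0]),
                                         pest_params)[0]
            at35 = development_increment(np.array([stage]), np.array([35.0]),
                                         pest_params)[0]
            assert at35 == at30 > 0

    def test_egg_rate_declines_above_optimum(self, pest_params):
        at30 = development_increment(np.array([EGG]), np.array([30.0]),
                                     pest_params)[0]
        at35 = development_increment(np.array([EGG]), np.array([35.0]),
                                     pest_params)[0]
        assert 0 < at35 < at30
        # mirrored slope: 35 °C behaves like 25 °C
        at25 = development_increment(np.array([EGG]), np.array([25.0]),
                                     pest_params)[0]
        assert at35 == pytest.approx(at25)

    def test_egg_rate_zero_when_cold(self, pest_params):
        inc = development_increment(np.array([EGG]), np.array([5.0]),
                                    pest_params)[0]
        assert inc == 0.0

    def test_transition_carries_over_excess(self, pest_params):
        pop = Population(1)
        pop.stage[0] = L1
        pop.dev[0] = 0.999
        temps = np.full(100, 30.0)
        step_development(pop, temps, pest_params)
        assert pop.stage[0] == L2
        expected_inc = pest_params.dl1 * (30.0 - pest_params.btl1)
        assert pop.dev[0] == pytest.approx(0.999 + expected_inc - 1.0)

    def test_starvation_scales_larval_development(self, pest_params):
        pop = larvae_at([(5, 5)], stage=L2)
        temps = np.full(100, 25.0)
        scale = np.array([0.5])
        inc = step_development(pop, temps, pest_params, starv_scale=scale)
        assert inc[0] == pytest.approx(
            0.5 * pest_params.dl2 * (25.0 - pest_params.btl2))

    def test_stage_pipeline_is_strict(self, pest_params):
        pop = Population(1)
        temps = np.full(100, 30.0)
        seen = [EGG]
        for _ in range(200_000):
            step_development(pop, temps, pest_params)
            if pop.stage[0] != seen[-1]:
                seen.append(int(pop.stage[0]))
            if pop.stage[0] == ADULT:
                break
        assert seen == [EGG, L1, L2, L3, PUPA, ADULT]


class TestWinterMortality:
    def test_zero_mean_zero_sd_no_deaths(self, rng):
        params = PestParams(me_mean=0.0, me_sd=0.0)
        pop = place_eggs(1000, True, params, rng)
        frac = winter_egg_mortality(pop, params, rng)
        assert frac == 0.0 and pop.alive.all()

    def test_certain_mortality_kills_all(self, rng):
        params = PestParams(me_mean=1.0, me_sd=0.0)
        pop = place_eggs(1000, True, params, rng)
        winter_egg_mortality(pop, params, rng)
        assert not pop.alive.any()

    def test_half_mortality_kills_half(self, rng):
        params = PestParams(me_mean=0.5, me_sd=0.0)
        pop = place_eggs(10_000, True, params, rng)
        winter_egg_mortality(pop, params, rng)
        assert int(pop.alive.sum()) == 5000

    def test_draw_truncated_to_unit_interval(self, rng):
        params = PestParams(me_mean=2.0, me_sd=0.1)
        pop = place_eggs(100, True, params, rng)
        frac = winter_egg_mortality(pop, params, rng)
        assert frac == 1.0


class TestEstablishment:
    def test_plateau_at_zero_starvation(self, pest_params):
        assert establishment_probability(0.0, pest_params) \
            == pytest.approx(pest_params.ml1a)

    def test_strictly_decreasing_in_starvation_time(self, pest_params):
        h = np.arange(0, 200)
        p = establishment_probability(h, pest_params)
        assert np.all(np.diff(p) < 0)

    def test_limit_zero_at_long_starvation(self, pest_params):
        assert establishment_probability(1e6, pest_params) < 1e-6

    def test_half_plateau_at_ml1c_hours(self, pest_params):
        assert establishment_probability(pest_params.ml1c, pest_params) \
            == pytest.approx(pest_params.ml1a / 2)

    def test_fed_larvae_never_die_of_establishment(self, pest_params):
        pop = larvae_at([(5, 5)] * 100)
        pop.starv_hours[:] = 0
        assert l1_establishment_check(pop, pest_params) == 0
        assert pop.alive.all()

    def test_starving_cohort_dies_out(self, pest_params, rng):
        pop = larvae_at([(5, 5)] * 1000)
        pop.starv_hours[:] = 1
        pop.estab_u[:] = rng.random(1000)
        for h in range(1, 400):
            pop.starv_hours[pop.alive] = h
            l1_establishment_check(pop, pest_params)
        assert np.count_nonzero(pop.alive) < 5


class TestStageHazards:
    def test_zero_mortality_never_kills(self, rng):
        pop = larvae_at([(5, 5)] * 1000, stage=L2)
        dev_inc = np.full(1000, 0.01)
        apply_stage_hazards(pop, dev_inc, 0.0, 0.0, rng)
        assert pop.alive.all()

    def test_cumulative_l2_mortality_matches_configured_value(self, rng):
        # 10 000 L2 run from dev 0→1 in uneven steps: deaths ≈ ml2·N
        n, ml2 = 10_000, 0.4
        alive = np.ones(n, dtype=bool)
        rngs = np.random.default_rng(7)
        dev = np.zeros(n)
        while np.any(dev < 1.0):
            inc = rngs.uniform(0.0, 0.05, size=n)
            inc = np.minimum(inc, 1.0 - dev)
            p = stage_hazard_probability(ml2, inc)
            alive &= rngs.random(n) >= p
            dev += inc
        deaths = n - alive.sum()
        se = np.sqrt(n * ml2 * (1 - ml2))
        assert abs(deaths - ml2 * n) < 3 * se

    @given(st.lists(st.floats(0.01, 0.3), min_size=1, max_size=20),
           st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_survival_independent_of_step_partition(self, parts, ml):
        # survival over dev 0→1 equals 1−ml however the stage is chopped up
        parts = np.array(parts)
        parts = parts / parts.sum()
        survival = np.prod(1.0 - stage_hazard_probability(ml, parts))
        assert survival == pytest.approx(1.0 - ml, rel=1e-9)

    def test_l3_and_pupa_share_one_mortality_budget(self):
        # survival across both stages multiplies to 1−ml3
        ml3 = 0.35
        s_l3 = 1.0 - stage_hazard_probability(ml3, 1.0 * 0.5)
        s_pupa = 1.0 - stage_hazard_probability(ml3, 1.0 * 0.5)
        assert s_l3 * s_pupa == pytest.approx(1.0 - ml3)


class TestMovement:
    def test_geometry_of_daily_ranges(self, pest_params):
        assert moves_per_day("sand") == 24
        assert moves_per_day("sandy_loam") == 6
        assert moves_per_day("silt_loam") == 4
        assert max_daily_displacement_cm("sand") == 33.9
        assert max_daily_displacement_cm("sandy_loam") == 8.5
        assert max_daily_displacement_cm("silt_loam") == 5.7

    def test_unknown_soil_type_rejected(self, pest_params):
        with pytest.raises(ValueError):
            pest_params.movement_interval("clay")

    def test_no_movement_when_food_sufficient(self, pest_params, rng):
        pop = larvae_at([(10, 10)])
        roots = roots_at([(10, 10)])  # Starv_i = 1
        moved = move_larvae(pop, roots, 0, "sand", pest_params, rng)
        assert moved == 0
        assert (pop.x[0], pop.y[0]) == (10, 10)

    def test_unlimited_uniform_food_means_no_movement(self, pest_params, rng):
        positions = [(x, y) for x in range(5, 15) for y in range(5, 15)]
        pop = larvae_at(positions)
        roots = roots_at(positions)
        for hour in range(24):
            assert move_larvae(pop, roots, hour, "sand",
                               pest_params, rng) == 0

    def test_movement_only_on_interval_hours(self, pest_params, rng):
        pop = larvae_at([(10, 10)])
        roots = RootState()  # no food anywhere -> always triggered
        moves = sum(move_larvae(pop, roots, hour, "silt_loam",
                                pest_params, rng) for hour in range(24))
        assert moves == 4

    def test_directed_step_toward_in_band_mass(self, pest_params, rng):
        pop = larvae_at([(10, 10)])
        roots = roots_at([(14, 14)], mass=0.0005)  # L1 band, distance 4
        move_larvae(pop, roots, 0, "sand", pest_params, rng)
        assert (pop.x[0], pop.y[0]) == (11, 11)

    def test_out_of_band_mass_not_sensed(self, pest_params, rng):
        pop = larvae_at([(10, 10)])
        roots = roots_at([(14, 14)], mass=0.004)  # L3 band, invisible to L1
        rng2 = np.random.default_rng(0)
        move_larvae(pop, roots, 0, "sand", pest_params, rng2)
        # random-walk step of one patch in some direction
        assert max(abs(pop.x[0] - 10), abs(pop.y[0] - 10)) == 1

    def test_horizontal_wrap_on_movement(self, pest_params, rng):
        pop = larvae_at([(0, 10)])
        roots = roots_at([(72, 10)], mass=0.0005)  # distance 4 across wrap
        move_larvae(pop, roots, 0, "sand", pest_params, rng)
        assert pop.x[0] == 75

    def test_mass_beyond_sensing_distance_not_seen(self, pest_params, rng):
        pop = larvae_at([(10, 50)])
        roots = roots_at([(10, 60)], mass=0.0005)  # distance 10 > sd 5
        rng2 = np.random.default_rng(1)
        move_larvae(pop, roots, 0, "sand", pest_params, rng2)
        assert max(abs(pop.x[0] - 10), abs(pop.y[0] - 50)) == 1


class TestFeeding:
    def test_single_l1_daily_removal(self, pest_params):
        pop = larvae_at([(10, 10)])
        roots = roots_at([(10, 10)], mass=0.1)
        removed = sum(feed_patch(roots, 10, 10, np.array([0]), pop,
                                 pest_params)[0] for _ in range(24))
        assert removed == pytest.approx(24 * 0.000015)
        assert pop.starv_hours[0] == 0

    def test_no_larvae_no_mass_change(self, pest_params, rng):
        roots = roots_at([(10, 10)], mass=0.1)
        pop = Population(0)
        fed = np.zeros((76, 100), dtype=bool)
        removed, ndr = feed_all_patches(pop, roots, pest_params, rng, fed)
        assert removed == 0.0 and ndr == 0
        assert roots.mass[0] == 0.1

    def test_equal_split_when_food_limits(self, pest_params):
        pop = larvae_at([(10, 10), (10, 10)])
        demand = 2 * pest_params.frl1
        roots = roots_at([(10, 10)], mass=demand / 2)
        removed, ndr = feed_patch(roots, 10, 10, np.array([0, 1]), pop,
                                  pest_params)
        assert removed == pytest.approx(demand / 2)
        assert ndr == 1  # the single segment was eaten out entirely
        assert np.all(pop.starv_hours == 1)

    def test_fully_eaten_segments_die_and_ledger_closes(self, pest_params):
        pop = larvae_at([(10, 10)], stage=L3)
        roots = roots_at([(10, 10), (10, 10)], mass=0.00002)
        removed, ndr = feed_patch(roots, 10, 10, np.array([0]), pop,
                                  pest_params)
        # L3 demand 0.00006 > 0.00004 available: everything eaten
        assert removed == pytest.approx(0.00004)
        assert ndr == 2
        assert not roots.alive[:2].any()
        assert roots.eaten.sum() == pytest.approx(0.00004)
        assert roots.closure_residual() < 1e-15

    def test_feeding_resets_starvation_episode(self, pest_params):
        pop = larvae_at([(10, 10)])
        pop.starv_hours[0] = 12
        pop.estab_u[0] = 0.5
        roots = roots_at([(10, 10)], mass=0.1)
        feed_patch(roots, 10, 10, np.array([0]), pop, pest_params)
        assert pop.starv_hours[0] == 0
        assert np.isnan(pop.estab_u[0])

    def test_starvation_index_ratio(self, pest_params):
        pop = larvae_at([(10, 10), (10, 10), (11, 10)])
        roots = roots_at([(10, 10), (11, 10), (11, 10)])
        starv = starvation_index(pop, roots)
        assert starv[0] == pytest.approx(0.5)  # 1 segment / 2 larvae
        assert starv[2] == pytest.approx(2.0)  # 2 segments / 1 larva


class TestPruning:
    def test_no_dead_segments_no_pruning(self, pest_params, rng):
        roots = roots_at([(10, 10)] * 50)
        assert apply_pruning(roots, 0, pest_params, rng) == 0
        assert roots.alive[:50].all()

    def test_pru_zero_disables_pruning(self, rng):
        params = PestParams(pru=0.0)
        roots = roots_at([(10, 10)] * 50)
        assert apply_pruning(roots, 10, params, rng) == 0

    def test_pruned_mass_enters_ledger(self, rng):
        params = PestParams(pru=1e9)  # probability capped at 1
        roots = roots_at([(10, 10)] * 20, mass=0.001)
        killed = apply_pruning(roots, 1, params, rng)
        assert killed == 20
        assert roots.pruned.sum() == pytest.approx(0.02 * 0.001 * 1000)
        assert roots.closure_residual() < 1e-15
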