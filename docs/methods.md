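# Methods

## Scope and structure

`rootwormsim` is an annual, temperature-driven, individual-based model of
the western corn rootworm and the root system of one representative corn
plant, on a 76 × 100 cm vertical soil cross-section at 1-cm³ resolution
(row spacing 76 cm; depth 1 m).  A replicate runs from Julian day 1 to the
damage-assessment day (planting day + days-to-assessment).  Processes are
updated hourly (development, mortality checks, movement, feeding — in that
order within an hour) or daily (segment spawning, root growth, pruning —
in that order at the start of a day); nothing is updated less often than
daily or more often than hourly.  Within a replicate the root sub-model
runs twice with one shared random stream: a pest-free twin and the pest
run, so that damage is scored against bit-identical control growth.

The hourly and daily orderings are a fixed convention: the underlying
biology gives no canonical within-step order, and results do depend weakly
on it, so it is documented here rather than configurable.

## Climate driver

The driving variable is an hourly temperature profile, one value per 1-cm
depth layer (1–100 cm), indexed from Julian day 1, 00:00, plus an hourly
volumetric water-content series at sowing depth covering the 2–3-week
germination window.  Files use long-format CSV (`hour,depth_cm,temp_c`;
`hour,wc_pct`); loading validates completeness and names the first gap.

The synthetic generator uses the classical damped-sinusoid solution of the
heat-conduction equation:

    T(z,t) = T̄ + A_a·e^(−z/d_a)·sin(ω_year(t − φ) − z/d_a)
                + A_d·e^(−z/d_d)·sin(ω_day·t)

Defaults emulate a temperate continental corn-belt season: mean 11 °C,
annual amplitude 14 °C, diel amplitude 3 °C, annual damping depth 180 cm,
diel damping depth 15 cm, phase day 109 (soil-temperature maximum around
Julian day 200).  Moisture is baseline 35 % (above the 30 % germination
threshold so that default runs emerge) plus Gaussian noise of 2 %, clipped
to [0, 100]; a 25 % drought preset exercises the failed-germination path.
Queries past the end of the moisture record hold the last value, since a
cold spring can push emergence slightly past the record.

What the generator does *not* emulate: weather fronts, rain-driven
moisture dynamics, soil-type-specific thermal properties, inter-annual
variability.  Passing tests on this driver show the model machinery is
correct and well-calibrated *under a smooth average season*; they do not
validate predictions for any real site-year.

## Root sub-model

Emergence: heat accumulates hourly at sowing depth (5 cm, profile centre)
as max(0, T − 10 °C)/24 °C·day from sowing; emergence fires at the first
hour the sum reaches 43 °C·day while the instantaneous temperature exceeds
10 °C and water content exceeds 30 %.

After emergence, node *n* (1–7) appears `node_day[n]` days later and each
developed node creates 0–3 new segments per day — uniform on {0,1,2,3},
the distribution being unspecified in the source literature — provided the
daily profile-average temperature lies strictly in (10, 30) °C.  The
averaging window for that gate is the day's 24 hours over all 100 depth
layers (a documented choice; "average soil temperature" has no canonical
window).  Expansion stops 56 days after emergence.  Placement: x = profile
centre ± N(0, hrrd[n]), wrapped at the edges like all horizontal
coordinates; y anchors at vrrdf[n] × node age (deeper as the node ages)
with proportional scatter (sd = 0.15 × anchor), clamped to 1–100 cm.

Each alive segment gains `rg` g/day for its first 30 days; segments on
patches fed upon the previous day grow at rg·(1 − min(1, pru)).  Natural
root senescence is deliberately absent — the only losses are feeding and
pruning — so the pest-free twin's mass is non-decreasing and its
cumulative growth is the damage denominator.

Spatial-placement and growth parameters (`rg = 0.0004` g/segment/day,
`node_day = 0,7,…,42`, `hrrd` increasing 3→20 cm, `vrrdf` decreasing
1.5→0.35 cm/day) are calibration parameters, chosen so that (a) nodes
appear weekly in shallow-to-deep order, (b) pest-free total mass rises
roughly linearly to ~4 g per 7.6 L by ~80 days after emergence, and
(c) young segments traverse the three larval attractiveness bands over
their first ~2 weeks.  They are defaults, not literature values, and are
config-overridable.

## Pest sub-model

**Oviposition** (previous autumn, so the run starts with the egg census in
place): depth bands 21/45/34 % in 0–10/10–20/20–30 cm, uniform within a
band.  Tillage: horizontal uniform.  No-till: top 2 cm excluded, horizontal
N(furrow, Hend = 10 cm) centred on the profile edge with wrap-around.

**Development**: dev += rate · max(0, min(T, 30) − baseline) per hour at
the individual's depth; eggs use the mirrored effective temperature
2·30 − T above the optimum, floored at zero.  Transitions fire at dev ≥ 1
with carry-over of the excess.  Underfed larvae (Starv_i < 1, see below)
develop at the fraction min(1, Starv_i).  Stage parameter defaults encode
degree-day totals of roughly 200 (egg, base 11 °C — a run input, as the
egg threshold is region-specific), 90 (L1), 100 (L2), 130 (L3) and 150
(pupa) above 10.5 °C; these are reconstructions from the literature's
reported stage durations, not canonical values.

**Survival**:

- Overwinter egg mortality: one fraction per replicate ~ N(0.55, 0.10)
  truncated to [0,1], applied uniformly at random before the season.
- L1: establishment-only mortality.  Establishment success over starvation
  hours h follows the decreasing three-parameter Hill curve
  Estab(h) = ml1a·ml1c^ml1b/(ml1c^ml1b + h^ml1b) with plateau ml1a = 0.95,
  half-time ml1c = 30 h, slope ml1b = 3.5.  Each starvation episode draws
  one uniform threshold u per larva; the larva dies at the first hour
  Estab(h) < u.  A full hourly ration ends the episode.
- L2, and L3+pupa jointly, carry development-linked hazards: per step,
  p = 1 − (1 − ml)^Δdev, so whole-stage mortality equals ml (0.40 and 0.35
  by default, per-replicate draws with sd 0.05) regardless of the
  temperature trajectory; the L3+pupa exponent is Δdev/2 so the two stages
  share one budget.

**Movement**: larvae get a move opportunity every 1/4/6 h in
sand/sandy loam/silt loam, taken only when Starv_i < 1.  Starv_i is the
ratio of alive root segments to larvae in the larva's patch (segments of
any mass band — the index counts segments, not attractive mass).  A moving
larva surveys its instar's band (L1: segment mass < 0.00094 g; L2:
0.00095–0.002 g; L3: 0.002–0.005 g; > 0.005 g is woody and invisible — the
0.00094/0.00095 gap is implemented as printed in the source scale) within
Chebyshev distance 5, steps one patch (diagonals allowed) towards the
richest patch with uniform tie-breaking, or takes a uniform step to one of
its 8 neighbours when nothing is in range.  Horizontal wrap, vertical
clamp.

**Feeding** (hourly, per patch): demand = Σ stage rates (0.000015 /
0.00003 / 0.00006 g/larva/h).  If alive patch mass covers demand, everyone
eats fully and resets their starvation clock; otherwise the available mass
is removed and all larvae in the patch accrue one starvation hour.
Segments are consumed smallest-first so fully eaten segments die one at a
time; their count is Ndr, the driver of pruning.

**Pruning** (daily): each alive segment dies with probability
min(1, pru·Ndr_yesterday/Nrs_alive); its standing mass enters the pruned
ledger.  The same parameter suppresses growth on fed patches (above).
Pruning-killed segments do not feed back into Ndr.

## Pruning calibration

`pru` is the one deliberately calibrated parameter, mirroring how the
original field calibration was done.  The calibration target is the
seasonal root-mass reduction caused by pruning, excluding direct feeding,
defined here as (twin mass − pest standing mass − eaten)/twin mass at
assessment — i.e. everything attributable to `pru` (randomised segment
deaths plus growth suppression).  A scan over pru ∈ [0.5, 5] at the
reference scenario (137 eggs/7.6 L, synthetic season, tillage, sand,
16 replicates × 5 master seeds) shows means of 0.27–0.34 at pru = 0.9,
centred in the 26–38 % band reported in the field literature; pru = 0.9 is
the frozen default.  The narrower metric "pruned-ledger mass / twin mass"
saturates near 13 % for any pru — heavy pruning starves larvae, which
lowers Ndr — and is not the calibration target.

## Damage assessment

Per node, loss % = 100 · (eaten + pruned)/(twin cumulative growth); the
denominator is cumulative growth rather than standing mass because natural
decline is excluded and losses are tracked against what grew.  NIS =
min(3.00, Σ loss %/100), two decimals; totals above 300 % cap at 3.00.
Yield loss = 16.5·ΔNIS % with uncertainty 1.9·ΔNIS propagated linearly.
A season in which the crop never emerged has no roots and scores 0.00.

## Replicates, seeding, determinism

Replicate r of master seed s is seeded with SeedSequence((s, r)); within a
replicate two child streams are spawned — roots (shared by pest and twin)
and pest.  Same config + seed reproduces results bitwise.  Ensembles
default to 40 replicates and report means, SDs and normal-theory 95 % CIs.
The reference scenario used throughout the tests runs 137 eggs on the
default synthetic season with 12–16 replicates, which keeps the full suite
at desk scale (a single replicate takes ~1 s) while the CI on the mean
pruned fraction (~±0.05) stays well inside the calibration band.

## Known limitations

- All Online-Resource-only numeric parameters (developmental rates and
  baselines, mortalities, Hill establishment fit, root placement tables)
  are literature-guided reconstructions; absolute NIS levels therefore
  differ from the original field calibration (the reference scenario here
  yields mean NIS ≈ 0.7 at 137 eggs), while the structural behaviours —
  phenology order, monotonicity in pest pressure, ledger closure, the
  pruning band — are the tested claims.
- No adult above-ground phase, no between-field dispersal, no flooding or
  moisture-dependent survival, no Bt/insecticide effects, single year only.
- The 2-D profile cannot represent true root-network topology; segments
  are independent, which is precisely why pruning is randomised rather
  than spatially propagated.
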