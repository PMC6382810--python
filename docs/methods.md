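# Methods

`gogrow` simulates the joint evolution of two heritable cancer-cell traits —
the intermitotic time τ ∈ [10, 40] h (inverse proxy for proliferation rate)
and the migration speed ν ∈ [0, 20] µm/h — in an off-lattice 2D population of
hard-disk cells competing for space, with mortality delivered either as
independent per-cell deaths (demographic stochasticity) or as spatially
clustered catastrophes (environmental stochasticity).

## Model

**Cells and space.** Cells are disks of diameter 20 µm in a circular domain
of radius R (default 1350 µm, a ~2.7 mm tissue; the radius is a config
field). Interactions are restricted to the Moore neighborhood (3×3 block) of
a 67 µm square hash grid, a strict superset of the 40 µm range at which any
cell can interfere with a division placement. The simulation clock advances
in 1-minute frames.

**Cell cycle and division.** Every cell counts its intermitotic time down
minute by minute; at zero it divides, keeping one cell at the original
position and placing the other exactly one diameter away at an angle drawn
uniformly from the set of angles at which the daughter neither overlaps a
neighbor nor leaves the domain. A neighbor at center distance d < 40 µm
blocks an arc of half-width arccos(d/40) around its direction; the boundary
blocks the outward cone where |x + 20u| > R − 10. When the blocked arcs cover
the full circle the cell is *surrounded*: it stops cycling and moving, with
the countdown paused in place. Arrest is re-evaluated continuously and is
reversible — a neighbor's death reopens space and the cell resumes cycling on
the following frame. Tangency (center distance exactly 20 µm) is not overlap
(numeric tolerance 10⁻⁹ µm), which makes hexagonal contact configurations
exact: three touching neighbors at 120° spacing block exactly 3 × 120°.

**Inheritance.** The newly placed daughter receives a mutated phenotype; the
cell retaining the original position keeps the parental one (`mutate_both`
switches to mutating both). Each trait independently improves, stays, or
diminishes with equal weight among the options that can remain feasible,
with step magnitudes uniform on (0, 4.5] h for τ and (0, 3] µm/h for ν.
Feasibility is the trait ranges plus an optional tradeoff boundary expressed
in normalized coordinates x = (40 − τ)/30, y = ν/20: *open* (no constraint),
*convex* (x² + y² ≤ 1), or *concave* ((x−1)² + (y−1)² ≥ 1) — the two
unit-radius arcs through the pure-specialist corners (1,0) and (0,1). A
drawn step that lands outside the feasible set has its magnitudes resampled
(up to 100 times, then clamped toward the parent), so daughters are feasible
by construction.

**Motility.** Non-dividing cycling cells perform a persistent random walk:
speed ν along a fixed heading for a persistence time drawn from N(80 min,
40 min) truncated to positive values (resampling; truncated mean 82.21 min),
then a fresh uniform heading. A 1-minute sub-move that would overlap a
neighbor is rejected whole — the position reverts and heading and
persistence are redrawn. A sub-move that would cross the domain boundary
arrests the cell permanently (nothing in the model can push it back inward).

**Mortality.** A per-cell death rate p_death (high: 1/7 per day, one death
per cell per week; low: 1/14 per day) is split between two channels by the
catastrophic fraction f. Demographic deaths are per-frame Bernoulli trials
with probability p_death·(1−f)·dt/1440, applied to every live cell and
removed at the end of the frame. Catastrophes kill every cell within 250 µm
of a uniformly placed center; victims wait an individual apoptosis delay
uniform on 6–15 h during which they are inert but still occupy space. The
delay is applied to catastrophic deaths only (configurable), keeping the
demographic-rate accounting exact.

**Adaptive catastrophe interval.** Events are spaced by
T_cat = (N_deaths/N)/(f·p_death), where N_deaths is the previous event's kill
count — events that overlap old gaps or the boundary (killing fewer cells)
shorten the next interval, holding the long-run catastrophic rate at its
target share. Two guards make this robust: the scheduler only starts once
the population reaches the expected capacity of one catastrophe region
(~446 cells at the default radii) — a tumor smaller than the region would
otherwise face near-certain annihilation by a full-cover event during the
bombardment that the zero-kill rule produces — and a zero-kill event
reschedules with the kill count floored at one cell (never below one frame).
The first interval is seeded with the expected interior kill count,
(250/R)²·N.

**Update order.** Each frame: (1) rebuild the hash grid; (2) fire a due
catastrophe, then sample demographic deaths; (3) advance apoptosis clocks
and remove expired cells; (4) visit every live, non-dying cell in a freshly
shuffled order — re-evaluate arrest, decrement the clock if cycling, divide
at zero (a division consumes the frame), otherwise move. Five named PCG32
streams (traits, motility, mortality, placement, schedule) drive all
randomness, so runs are bit-reproducible for a given seed and changing one
process (e.g. mortality) does not perturb the draw sequence of another.

## Numerical and performance choices

The per-frame update is compiled (numba). Cached per-cell surround status is
invalidated whenever any occupancy change (birth, removal, committed move)
occurs within 40.5 µm — observationally identical to re-evaluating every
cell every frame, and the dominant saving in at-capacity populations where
almost everything is arrested. Bin membership is updated lazily: a moving
cell keeps its frame-top bin (sub-moves are ≤ 0.34 µm against a 27 µm Moore
slack), while removals unlink immediately so their slots can be reused.
Surround coverage uses an exact interval-union sweep with a 10⁻⁹ rad
tolerance on the free measure.

## Synthetic initial states

There is no external data; all initial states are generated.

* **Single founder** (default): one cell, least aggressive phenotype
  (τ = 40 h, ν = 0), at the center.
* **Dense-packing initializer**: stands in for a completed growth run when a
  full-scale fill would take hours. It lays a hexagonal lattice at the
  spacing (22.55 µm) that reproduces the reference filled-tumor density of
  13,000 cells in the default domain, with cycle clocks at uniformly random
  phases. At that spacing every interior cell is completely surrounded, so
  divisions resume exactly where deaths open space. Capacity experiments
  start it from the fully evolved aggressive generalist (τ = 10 h,
  ν = 20 µm/h) — the open-boundary endpoint of a filled tumor — because
  sustained migration is what lets a filled population keep refilling
  mortality gaps; with a non-migratory phenotype, catastrophe craters refill
  only by slow frontal division and the population sags far below capacity.

What the lattice does not emulate: the irregular contact topology and
phenotype rings of a genuinely grown tumor, and its looser (jammed) density
— see the capacity note below. Conclusions drawn from packed-start runs
therefore concern mortality/refill bookkeeping, not spatial trait structure.

## Measured model properties

* **Jam density.** Growth from a founder halts (every cell surrounded or
  boundary-arrested) at an area packing fraction of ≈ 0.52, independent of
  domain radius over 300–700 µm and of the starting phenotype. Irreversible
  contact placement with no pushing jams near random-sequential-adsorption
  density, well below hexagonal close packing (0.91); turnover does not
  ratchet the density upward. The extrapolated self-filled capacity of the
  default domain is therefore ≈ 9,500 cells, whereas the reference capacity
  used by the packed initializer is 13,000 — the latter is the quoted
  property of the system the initializer emulates, not a prediction of this
  engine's own jamming. The packing-fraction test asserts the reference
  extrapolation band and documents this known gap.
* **Death-rate calibration.** With the packed initializer, one simulated day
  under the high rate removes ≈ 1,700–1,800 cells (reported to the nearest
  thousand: 2,000) and under the low rate ≈ 900 (reported: 1,000), averaged
  over five seeds.
* **Scheduler compensation.** Over 10 days at capacity, fully catastrophic
  mortality realizes a deaths/day within ~6–10% of the all-demographic value
  for the same initial state; both populations relax to the model's own
  carrying capacity and the adaptive interval tracks it.

## Scaled-down selection experiments

The two-phase selection analyses run in a 500 µm-radius domain (natural
capacity ≈ 1,300 cells) for 90 simulated days under the high death rate,
from the least aggressive founder — sizes chosen so a five-seed panel per
condition completes on a desk machine. During expansion all three boundaries
select migration upward from ν = 0; after space fills, demographic death
swings selection toward fast proliferation (concave runs end
proliferation-dominant with low ν), while 100% catastrophic death keeps
migration under selection (concave endpoint ν roughly 2–3× the demographic
one). Starting from one cell under a per-cell death rate, lineage extinction
is a genuine branching-process outcome (the founder dies before first
division with probability ≈ 0.2 at the high rate); endpoint statistics
condition on persistence by scanning seeds deterministically and keeping the
first five surviving runs, as is standard for birth–death processes started
from a single individual.

## Known limitations

2D only; no pushing, adhesion, or compression (hard non-overlap); no
resource fields, vasculature, or immune interactions; death rate is
phenotype-independent; boundary arrest is permanent; mutation acts on both
traits independently at every division. The 50-hour slowest division time
mentioned in some descriptions of this model class conflicts with the
τ ≤ 40 h trait range; the trait-range value is used throughout.
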