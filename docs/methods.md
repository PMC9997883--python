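# Methods

## The Act-CPM

The cellular Potts model represents every cell as a set of lattice pixels on
a 150x150 torus. Dynamics proceed by copy attempts: a source pixel tries to
copy its cell identity into a Moore-neighbour target pixel, and the attempt
is accepted with the Metropolis rule `P = 1` if `delta_H <= 0`, else
`exp(-delta_H / T)` at temperature `T = 20`. One Monte Carlo step (MCS), the
time unit, comprises `width x height` attempts, each drawing a uniform
source pixel and a uniform Moore neighbour.

The energy has four parts. Adhesion charges `J(kind_i, kind_j)` per Moore
pair of pixels belonging to different cells. Volume and perimeter are soft
constraints `lambda_X (X - X*)^2` per cell, with the perimeter measured as
the number of Moore pairs `(p in cell, q not in cell)`. The Act term exists
only as a contribution to `delta_H`:
`-(lambda_act/max_act) (GM_act(source) - GM_act(target))`, where `GM_act(p)`
is the geometric mean of the activities of `p` and its same-cell Moore
neighbours (zero for background, and zero as soon as any included activity
is zero). A pixel gained by a cell with Act feedback is assigned activity
`max_act`, which decays by 1 per MCS and floors at 0; pixels gained by
background or by cells without the feedback get activity 0.

Parameters per cell kind (dimensionless CPM units): T cell — target volume
500 (lambda 30), target perimeter 260 (lambda 2), adhesion 20 to
background; keratinocyte — volume 750 (lambda 30), perimeter 330
(lambda 10), adhesion 200 to other keratinocytes, 2 to the T cell, 20 to
background. Only `(max_act, lambda_act)` vary during evolution.

### Choices the model statement leaves open

* **Acceptance at `delta_H = 0`** is acceptance with probability 1
  (the standard CPM convention).
* **Adhesion/perimeter neighbourhood** is Moore, matching the neighbourhood
  used for `GM_act`.
* **`GM_act` includes the centre pixel** and only same-cell neighbours.
* **`max_act` stays continuous**: mutation is continuous and no rounding
  rule is imposed; decay remains -1 per MCS.
* **Cell annihilation is allowed** (a cell may lose its last pixel); it is
  detected and, in fitness evaluations, scored 0.

### Implementation

Production simulations run through a numba kernel that is *rejection-free*:
attempts whose source and target share a cell id can never change the
state, so the kernel draws the geometric waiting time to the next
id-mismatched attempt (mismatch probability `B / 8N`, with `B` the
incrementally maintained count of ordered unlike Moore pairs) and then picks
such a pair uniformly by rejection from the border-pixel list. Because
skipped attempts are exactly the no-ops of the naive sweep, the distribution
of states per MCS is identical to the literal `width x height`-attempt
convention; the test suite cross-validates the kernel's `delta_H` against a
plain brute-force reference implementation and checks that incremental
volumes, perimeters and border counts equal a from-scratch rebuild after
long runs. Activity is stored as the MCS at which each pixel was gained,
making the per-MCS decay implicit. Each simulation owns an xorshift128+
random-number state seeded from one integer, so runs are reproducible and
independent.

## Environments

**Free:** one T cell seeded as a compact disc of its 500-pixel target volume
at the grid centre, then 500 MCS of burn-in. The disc shape is a
convenience; any compact seed relaxes well within the burn-in.

**Skin:** 31 keratinocytes seeded one at a time at uniformly random
positions whose (25-pixel disc) footprint is free, each grown for 50 MCS
before the next is placed. During seeding the keratinocyte perimeter target
is 200 — rounder cells do not entangle or shear apart while growing — and
the targets switch to the final 330 after a further 500 MCS of
equilibration, when the first-seeded keratinocyte's pixels are reassigned to
the T cell (activity reset to zero; the T cell then shrinks toward its own
500-pixel target during the simulation). A fresh tissue is generated for
every evaluated individual, with its seed recorded; reusing one tissue
would risk selection exploiting tissue-specific geometry.

## Fitness

The T cell's centroid is logged every 5 MCS with torus-consistent
(minimal-image) unwrapping. Every pixel the cell ever occupies — recorded at
copy acceptance, not merely at log points — accumulates into the explored
area; fitness is explored pixels / 500. Connectedness
`C = sum_k (n_k/N)^2` (the probability that two random pixels of the cell
lie in one Moore-connected component) is evaluated at every log point; a
value below 0.9 at any checkpoint marks the cell broken and zeroes its
fitness, as does annihilation. Checking every MCS instead of every log
point is available (`check_every_mcs`) and changes results negligibly at
~25x the measurement cost.

## Evolution

(mu + lambda) selection with `N_pop = 10`, `lambda = 3`: each generation
mutates every parameter of every parent on the log scale
(`x -> exp(ln x + eps)`, `eps ~ N(0, sigma_mut)`, sigma 0.6 in generations
1–5 and 0.2 after), evaluates all 40 individuals with fresh simulations
(parents are re-evaluated, so fitness stays an unbiased single-sample
estimate for everyone), and keeps the 10 fittest. Ties are broken in a
uniform random order drawn from the run's seed stream. Initial genotypes:
(5, 5) in empty space; (5, 100) in skin, where tissue resistance demands a
higher protrusion force before any motion is possible.

The consensus optimum across runs drops non-converged runs — those whose
population mean of either parameter changed by at least 20% (raw scale)
between generations G-9 and G — then pools survivor values from the last 10
generations of the remaining runs, averages on the log scale, and rounds to
the nearest 5. The "either parameter" reading is the stricter
interpretation of the convergence wording; `mode="both"` implements the
alternative. Around an optimum, a 13-point cross-shaped sweep
`exp(ln x* +/- i * 0.1), i = 0..3` per parameter is provided, as are the
named trajectory points (5,5), (50,17), (110,30), (70,150), (50,1185).

## Track statistics

Step-based speeds are displacements between consecutive log points divided
by the 5-MCS interval. The pooled MSD uses all overlapping displacements,
each lag weighted by the number of *independent* displacements
(`sum_tracks floor(n/lag)`), because overlapping displacements share data.
Fuerth fitting is two-stage: a rough weighted fit over the full window
yields `(D0, P0)`; the final weighted fit runs on the log scale (fitting
`ln D`, with `P` bounded positive) on lags `>= P0`, discarding the
sub-persistence lags where lattice cells do not truly move. Both stages
ignore lags beyond a quarter of the largest lag: the MSD tail rests on a
handful of strongly correlated displacements and, when included, can swing
the persistence estimate by tens of percent between seeds
(`max_lag_fraction=None` restores the full window).

The autocovariance of step displacement vectors is fitted with
`c * exp(-dt / sqrt(Psq))` — parameterising `P^2` keeps the persistence
positive — over a window that (i) drops lags up to `0.5 * P_msd` (small-lag
lattice artefacts) and (ii) drops lags beyond `3 * t5`, where `t5` is the
first *retained* lag at which the autocovariance falls below 5% of its
value at the smallest retained lag; beyond that the curve is noise around
zero. The 5% reference uses the smallest retained lag (not an extrapolated
lag-zero amplitude) because the pre-filter has already removed the
artefact-prone region; a curve that never decays below 5% leaves the window
open and flags the fit. Starting values are `(c = 1, Psq = P_msd^2)`.

Grouped estimates split 30 tracks into 6 groups of 5 by simulation order
and report mean +/- SD over the six per-group estimates of speed and both
persistence measures.

## Run-and-pause reference model

A point cell alternates straight runs (duration `t_free`, speed `v_free`,
direction uniform on the circle, redrawn after every pause) with stationary
pauses (`t_pause`), starting with a run at t = 0; positions are sampled at
unit time steps with linear interpolation inside runs. The walk is planar,
matching the pixel-based fitness. Fitness marks every integer lattice point
within `r = 13` of any sampled position, each point once, and divides by
the exact disc area `pi r^2` (not the rounded 530). The counter is exact:
candidate points come from the disc around the current position, points
covered by the previous position are skipped (they are already recorded),
and the remainder pass through a reusable open-addressing hash table.
Evolution uses the same GA over `(v_free, t_free, t_pause)` from (1, 1, 1)
for 25 generations. Because parameters map directly onto behaviour, the
model predictably drives `v_free` and `t_free` up and `t_pause` down until
consecutive discs no longer overlap, after which fitness saturates at one
disc per time step and the parameters drift.

## Synthetic ground truth

The persistent-random-walk generator is an angular-diffusion walk: heading
increments are Gaussian with variance `2 dt / P`, giving a step-vector
autocovariance that decays exactly with time constant `P`, while the step
speed is exactly `s`. Its own tests verify the decay constant empirically.
It emulates the statistics the analysis stages assume — it does not emulate
CPM-specific features such as small-lag lattice artefacts, breakage, or
environment-induced intermittency, so passing recovery tests demonstrates
correctness of the estimators, not realism of the walk. Noiseless Fuerth
and exponential curves provide machine-precision oracles for the fitters,
and four tiny hand-built lattices (a square cell, two touching cells, an
equal split, a boundary-straddling cell) anchor the energy and
connectedness arithmetic.

## Problem sizes for routine runs

Full replication of the evolutionary endpoints (10 runs x 50 generations x
40 individuals x 10,000 MCS per environment) is an overnight,
embarrassingly parallel computation. The bundled experiments
(`evocpm.experiments`) run the identical machinery at reduced sizes chosen
as the smallest that still express the qualitative trends: empty-space
evolution on a 100x100 grid with 2,000-MCS evaluations for 15 generations,
and run-and-pause evolution with 2,000-step walks for 25 generations. At
these sizes a 10-run trend experiment completes in minutes on one core.
Fifteen generations sit near the edge of the initial fitness plateau at
(5, 5): most, but not always all, runs escape it in time (see the test
suite's trend checks), exactly as the drift-driven escape mechanism
predicts.

## Known limitations

* 2D lattices only; no chemotaxis, division, or death beyond passive
  annihilation.
* Persistence estimates approach the simulation length for evolved cells in
  empty space and are then order-of-magnitude estimates by nature.
* The rejection-free kernel reproduces per-MCS statistics exactly but not
  the attempt-by-attempt random stream of a naive implementation; seeds are
  comparable only within one engine.
* Fitness evaluation is single-sample; selection near the plateau operates
  on noisy fitness, which is faithful to the modelled process but makes
  short runs sensitive to drift.
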