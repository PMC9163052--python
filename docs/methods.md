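# Methods

## The model

`stemdish` simulates a hypothetical adult tissue as a square lattice ("dish")
of meshes, at most one cell per mesh.  Four cell types live on it:

* **S** — stem cells: divide (rate `r_s = 56.4`), die (`gamma_s = 0.0423`),
  transform to P (`w_p = 0.329`), and move (`m_s = 2.82`).
* **P** — progenitor cells: divide (`r_p = 32.9`), die (`gamma_p = 0.01504`),
  transform to S (`w_s = 0.1645`), move (`m_p = 0.94`).
* **A**, **B** — terminal cells: they only die (`gamma_A = 0.003`,
  `gamma_B = 0.0034`) and secrete one signalling species each (A → S1,
  B → S2).

All rates are per cell per unit model time.

Each dividing cell carries integer counts of two cytoplasmic fate
determinants X and Y.  Inside a stem cell they obey a bistable
mutual-repression switch,

    dx/dt = iota_x * beta^n / (beta^n + y^n) - gamma x      (and symmetrically),

with `iota_x = 85`, `iota_y = 100`, `beta = 45`, `n = 4`, `gamma = 1`: two
stable states, one x-dominant (fate S) and one y-dominant (fate P).  Inside a
progenitor the switch gains self-activation,

    dx/dt = (alpha_x + eps1) x^n/(beta^n + x^n) + iota_x beta^n/(beta^n + y^n) - gamma x,

with `alpha = iota = 30`, `beta = 47.5`, `gamma = 0.38`: three stable states
(balanced → P, x-dominant → A, y-dominant → B).  The local signal counts
enter through the saturating coefficients `eps_i = a*s_i/b` for `s_i <= b`,
else `a` (`a = 10`, `b = 15`), which grow the A (B) basin where S1 (S2) is
abundant — this is how a daughter cell "reads" its location.

The two signal species are produced at A- and B-occupied meshes
(`alpha = 220` repressed by the other species with `beta = 2`, `n = 4`),
decay (`k = 0.5`), and hop between orthogonal neighbours with the propensity
`D/h^2` per loaded mesh (`D = 110`, `h = 1`) printed in the model's rate
table.  That propensity is deliberately *not* proportional to the molecule
count; a `diffusion_scales_with_count` switch provides the mass-action
variant.

## Stochastic simulation

The dish evolves by an exact Gillespie algorithm over 24 reaction channels
(4 determinant channels + division + death + transformation + movement for
each dividing compartment; terminal deaths; signal production, decay and
diffusion per species).  Per-mesh total propensities are kept in a Fenwick
tree, so each event costs O(log N) plus a handful of local propensity
refreshes; the loop is jit-compiled and sustains ~10^6 events/s on one core.

Division draws Binomial(n, 1/2) partitions of the mother's X and Y counts,
places one daughter on the mother's mesh and the other on a uniformly chosen
empty 8-neighbour, and calls each daughter's fate by integrating the
deterministic switch (RK4, dt = 0.01) from its inherited counts until the
trajectory enters the unit ball of a stable fixed point (stalls on a
separatrix resolve to the dividing fate P).  Daughters of progenitor mothers
are classified with the signal-effect coefficients of the mesh they occupy at
birth.  A daughter that crosses systems (an S mother producing a P daughter,
or a transformation event) re-draws its determinants uniformly from the
cached basin of its new attractor, computed on the 151x151 integer grid of
the signal-free switch.  Divisions are *gated*: a dividing cell with no empty
placement neighbour contributes zero division propensity, which keeps the
algorithm exact; the movement channel (relocation to a uniformly chosen
empty mesh anywhere in the dish) exists precisely to relieve this blocking
and becomes a logged no-op when the dish is full.

The stem X-synthesis rate carries a density feedback
`iota_x(n) = 2 * 85 * n0 / (n0 + n)` where `n` is the current census of
dividing cells and `n0` its value at initialization: strictly decreasing,
equal to the table value at the calibration census, doubling at an empty
dish.  The model only constrains the sign of the derivative; this hyperbola
is the package's choice.  It tilts daughters toward S self-renewal when
dividing cells are scarce (e.g. after injury) and away from it when they are
abundant.

### Termination

A run stops when progenitor cells have gone through the configured number of
divisions on average (default 50).  The statistic is the cumulative count of
P-division events per living P cell.  (A per-cell counter mean cannot serve
here: in the model's own regime differentiating divisions dominate, so a P
lineage survives only a couple of divisions and the mean of per-cell counters
plateaus near 1-2 regardless of run length.  Per-cell counters are still
kept — daughters inherit the mother's counter plus one, transformed cells
reset to zero — and are exported for inspection.)  Because division is
space-limited, simulated time per mean division is set by the terminal-cell
turnover (`gamma_A`, `gamma_B`), about 14 time units per division on the
dishes used here.

### Snapshots

`n_shots` (default 500) dish snapshots evenly spaced in simulated time are
retained.  Since the stopping time is not known in advance, the engine keeps
a 2x buffer at a provisional spacing and doubles the spacing (discarding
every other snapshot) whenever the buffer fills; the final state is always
appended, and the recorded set is subsampled to exactly `n_shots` frames.

## Dish geometry and initialization

Built-in patterns: circle (radius R, inner disk r), square, rectangle and
triangle (inner region at half linear size), or any user label matrix
(0 outside, 1 A-territory, 2 B-territory).  Every valid mesh starts occupied
by its territory's terminal type with 100 molecules of its own signal;
dividing cells are then scattered uniformly, by default S on 1/30 and P on
1/15 of the meshes (the observed S:P transformation balance w_s : w_p = 1:2,
totalling 10% dividing cells), their determinants drawn from the matching
signal-free basins.  Injuries remove every cell in a mask when the mean
division statistic crosses a trigger; signal molecules are left to decay.

## Pattern score

The initial pattern defines a d x d template (+1 on A-territory, -1 on
B-territory) and penalty (1 outside the dish) filter pair.  Snapshots are
encoded (+1 A, -1 B, 0 otherwise), zero-padded to 2d x 2d, and both filters
slide through d+1 offsets along one axis (the offset count a d-wide filter
admits against a 2d frame; a full 2-D sweep is available as `sweep="full"`);
the shot's raw score is max_i(t_i - p_i).  Scores are normalized by the
*initial configuration's* raw score and clamped to [0, 1].  Normalizing by a
per-series min-max instead would force every decreasing series to end at 0
and is therefore not used; with the reference normalization the series reads
directly as "similarity to the intended pattern".

## Signal transport and the two diffusion rules

Two neighbour-selection rules are implemented for the diffusion channel.
`uniform` — the default — moves the molecule to a uniformly chosen orthogonal
neighbour (physical diffusion).  `weighted` implements the alternative
prescription that a neighbour already holding more molecules is more likely
to receive the hop (probability proportional to 1 + its count), an
anti-diffusive winner-take-all sharpening.

The uniform default matters mechanistically.  Territory defence works by
*suppression delivery*: the dense signal around a territory's own terminal
cells flows downhill into any mesh where a wrong-type cell appears, and a few
tens of molecules there (against `beta = 2`) keep the intruder's own signal
production shut off until it dies.  Under the uphill rule that flux vanishes
— molecules pile onto already-loaded meshes — so an intruder only has to
outlive the residual opposing signal (~15 time units at `k = 0.5`, against a
~300-unit terminal lifetime) to erect its own self-sustaining signal pillar.
The late-run spatial states confirm this: uphill transport produces a
fine-grained self-stabilizing mosaic of single-mesh territories, while
uniform transport keeps coherent domains.

## Scale and the signal penetration length

With `D = 110` and `k = 0.5` a lone molecule travels ℓ = sqrt(D/k) ≈ 15
meshes before decaying.  Pattern maintenance therefore has an intrinsic
length scale: a territory much thinner than ℓ cannot keep the opposing
species' molecules (and fate bias) out, and the model predicts — this is its
own dish-size result — that small dishes gradually lose their pattern while
large ones plateau.  Desk-scale protocols in this package use smaller dishes
at unchanged parameters, so they sit partly inside that erosion regime:
on the radius-20/inner-10 dish the signal-on score declines slowly toward
~0.2-0.3 by 50 mean divisions instead of levelling at the full-scale
plateau, while remaining several-fold above the signal-free score.
Full-scale protocols (radius 50, inner 25, D = 110) are provided as recipes.

## What the generator does and does not emulate

The dish is a caricature of an adult tissue: one cell per mesh, no mechanics
(division is blocked without an empty neighbour; movement is random
relocation, not pushing), signals are integer molecule counts per mesh, and
terminal cells are inert except for death and secretion.  Passing tests
demonstrate internal consistency of the stochastic model and its mean-field
reduction — homeostasis of the four abundances, pattern retention with
signalling, pattern loss without — not quantitative agreement with any real
tissue.

## Numerical choices

* Fate calling: RK4 with dt = 0.01, capture ball radius 1.0 around stable
  fixed points, 10^5-step cap, drift tolerance 1e-10; ties resolve to P.
* Fixed points: multi-start `scipy.optimize.root` on a 13x13 seed grid,
  deduplicated at distance 0.5, stability by the analytic 2x2 Jacobian.
* Progenitor fate tables: the signal effect takes b+1 distinct values per
  species, so stable fixed points are pre-solved for all (b+1)^2 coefficient
  pairs and the SSA classifies against the table of the daughter's mesh.
* An attractor is labelled dominant (A or B) when its smaller coordinate is
  below 10 molecules; balanced attractors keep both coordinates near the
  half-saturation constant (~47.5 at table parameters), so the margin is wide.
* The Fenwick tree is rebuilt from scratch every 2^20 events to cancel
  accumulated floating-point drift.
* The mean-field fixed point follows the closed form with the progenitor
  mixed-division rate read consistently from the density equations (the
  summary table of the source model prints a different symbol in two entries;
  the integration test confirms the consistent choice).

## Known limitations

* The per-mesh (count-independent) diffusion propensity printed in the rate
  table makes sparse signal tails hyper-diffusive; it is kept for fidelity,
  with the mass-action variant behind a flag.
* Termination time is death-rate-limited, so full-scale runs are long; the
  engine is exact (no tau-leaping).
* The mean-field effective rates are emergent, not inputs; they can only be
  measured from event logs (`measure_effective_rates`), not prescribed.
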