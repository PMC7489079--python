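# Methods

## Model overview

`mscarbon` simulates one day of carbon allocation at a time on a static
plant structure.  A simulation day runs: allometric biomass initialisation
(first day only) → per-organ demand assembly → supply attachment →
up-scaling to the working scale → pairwise topological distances →
source–sink flow computation → down-scaling to organs → dry-mass update.
The structure is fixed within a season: no new metamers are created, and
there is no within-day sub-stepping.

The allocation rule is a proportional source–sink model: each source
empties itself completely every day, splitting its carbon across all sinks
by demand × proximity.  Two consequences are worth keeping in mind when
interpreting output.  First, sinks on the path between a source and a
distant sink do not intercept flow — the formalism is deliberately
path-blind beyond distance.  Second, because each source is normalised
independently, total carbon is conserved exactly by construction; the
conservation residual reported by `AllocationResult` is a numerical
self-check, not a fitted quantity.

## Distances and geometry

The distance between two same-scale elements is measured along the
topology through their greatest common ancestor (GCA):

* lengths of the elements strictly between each endpoint and the GCA,
* each endpoint's semi-length (Euclidean distance base → barycentre),
* if the GCA is neither endpoint, the Euclidean gap between the bases of
  the two path elements directly borne on the GCA.  This term is zero at
  the metamer scale (siblings share their parent's top) and non-zero at
  coarse scales, where laterals insert at different points along a long
  element.

Conventions where the formalism leaves room:

* **Self-distance is zero**, so an element that is both source and sink
  weights itself with the maximum proximity factor `f = 1`.
* **Coarse length** is the sum of component lengths.  For a branched
  coarse component this overstates the traversal length of a path passing
  through it; the distortion is accepted and documented here rather than
  hidden (an entry-to-exit path length would be an alternative).
* The **base gap** metric is the 3-D straight-line distance between base
  points.
* The coarse **barycentre** is the mean of component barycentres weighted
  by their lengths; if all component lengths are zero the plain mean is
  used.  The coarse **base** is the base of the base component (the unique
  component whose parent lies outside the complex).  The base coordinates
  of the scale root are stored on its complex chain.

All lengths and coordinates are metres internally.  This matters because
the proximity factor adds 1 to the distance before exponentiating: the
same tree expressed in centimetres would give different allocations, so
readers/writers carry an explicit `unit` flag (`m`/`cm`/`mm`).

The all-pairs computation uses binary-lifting GCA queries plus root-path
prefix sums of element lengths, shared across pairs, so cost is
near-quadratic in the number of components at the working scale rather
than in metamers.  Agreement with an explicit path-walk oracle is asserted
to 1e-9 relative in the test suite.

## Demands, activities, respiration

Sink activity (g g⁻¹ °C⁻¹) per organ class:

| class    | activity                                                      |
|----------|---------------------------------------------------------------|
| fruit    | normalised Gompertz derivative, a=63.703, b=−4.896, c=−0.00104 |
| shoot    | normalised Gompertz derivative, a=2.406, b=−2.84, c=−0.00165   |
| old wood | constant 3.1e−5                                               |
| leaf     | lookup table, clipped to [0, 1.9e−3]                           |
| root     | derived: Σ shoot demand / 4.5                                  |

The Gompertz activity is evaluated in its ratio form
`(a·b·c·exp(b·exp(c·G)+c·G)) / (a·exp(b·exp(c·G)))`, which simplifies to
`b·c·exp(c·G)`; both forms and the numerical derivative of log dry weight
agree to the tolerances asserted in the acceptance tests.  Thermal time is
accumulated as daily mean temperature above a 4.5 °C base, floored at zero.

The content of the leaf-activity lookup table is not published; the default
is a constant mid-range value (9.5e−4) in a user-editable table keyed by
GDD, always clipped to the documented bounds.  Epicormic shoots have no
published Gompertz coefficients and reuse the proleptic ones with a logged
warning.

Demand conversion: the activity equation yields dry-matter demand (g),
converted to carbon by dividing by the assimilate-to-biomass ratio
(2.105263158 g DM per g C) so demands and supplies (g C) are commensurate;
allocated growth carbon converts back by the same ratio, making the
"fully satisfied organ gains exactly its dry-matter demand" round trip
exact.

Respiration is split into a Q10 maintenance term (∝ dry mass) and a growth
term (∝ maintenance + growth demand).  The published source for the
coefficient values is not reproduced here, so the defaults are zero —
respiration off — and any non-zero use must set `q10`, per-organ
maintenance coefficients and the growth-respiration coefficient
explicitly.  Demand is pooled: when supply is short, maintenance has no
priority over growth; each organ's received carbon satisfies its demand
components proportionally.  Old-wood activity is implemented as the
constant value; a GDD-dependent alternative can be swapped in through the
species parameters.

## Scales

Group construction always partitions the metamer set into connected
subtrees; the coarse parent and edge type come from the single finest-scale
edge crossing the group boundary, and a violation (disconnected group) is
an error naming the group, never a silent fix.  Decisions taken where the
scale definitions are underspecified:

* **Branching order** increments at each branching (`+`) edge from the
  trunk base — the standard tree-graph convention.
* **TBS**: a shoot is a maximal current-year subtree bearing ≥ 1 leaf,
  wherever borne (including the trunk apex); leafless current-year growth
  stays with its supporting trunk or branch; a branch group is the
  non-shoot part of a lateral subtree borne on the trunk.
* **BR1**: trunk (with its own shoots) plus each entire first-order branch
  subtree, shoots included.
* **FU**: maximal connected sections of wood aged exactly one year,
  together with the current-year shoots borne on them; older wood forms
  connected supporting groups; current-year shoots borne directly on old
  wood (epicormics) merge into their supporting group with a logged count;
  a tree with no 1-year-old wood degenerates to a single unit covering
  current-year growth.
* Groups that would contain zero metamers are dropped with a log warning.
* The root compartment is one opaque element, always its own group.

A built scale is materialised as a fresh three-scale tree
(plant / group / metamer); grouping is always computed from the metamer
scale, so scales never need to nest within each other.

## Synthetic trees and the supply stub

The generator emulates a young apple tree: a vertical trunk of growth
units whose year increases towards the apex, Poisson-distributed
first-order branches on older trunk growth units, branches ageing towards
their tips, current-year leafy shoots terminating branches and borne
laterally on 1-year-old wood, leaves on every current-year metamer and
fruits on a configurable fraction of shoots (initial fruit dry weight 8 g,
identical for all fruits).  Defaults: 4-year-old tree, 5 cm wood metamers,
2 cm shoot metamers, 0.003 m² per leaf, fruit probability 0.6 per shoot —
values chosen once as architecturally plausible for a young orchard tree.
One seeded RNG stream drives all draws, so a seed fully determines the
tree.

The supply stub assigns each leaf `leaf_area × max_rate × exp(−k·depth)`
g C day⁻¹ with depth measured from the canopy top (defaults 6 g C m⁻²
day⁻¹, k = 0.5 m⁻¹).  It reproduces the one property the analyses depend
on — shaded leaves assimilate less — and nothing else: no diurnal course,
no diffuse/direct split, no leaf-angle effects, no photosynthesis
response curves.  Consequently, passing tests demonstrate the correctness
of the allocation machinery under realistic gradients of supply, not the
radiative fidelity of any particular canopy.

## Analyses

* **Comfort index**: per fruit and radius, assimilated carbon within the
  (Euclidean, barycentre-to-barycentre) neighbourhood divided by the
  number of fruits there (the focal fruit counts itself).  Correlation is
  Pearson by default (Spearman switchable), pooled over fruits, with
  Bonferroni correction 0.05/11 across the radius set
  {0.05 … 1.35 m}.  Fewer than three fruits or zero variance yields a
  flagged missing correlation.
* **Cross-scale comparison**: per fruit-bearing coarse component, mean
  metamer-scale fruit growth vs coarse-scale growth; RMSE and CV of RMSE
  (RMSE / reference mean).  In the common-pool limit (h = 0) the CV is
  analytically zero at every scale — the strongest cross-scale
  correctness check, asserted to 1e-9.
* **Distribution RMSE**: both samples z-scored (min–max switchable),
  binned on a shared equal-width grid (default 20 bins, reported), RMSE of
  count *fractions* so unequal sample sizes compare fairly.

## Numerical choices

* Flows in double precision; conservation asserted at 1e-9 relative.
* Coarse barycentre identity asserted at 1e-12.
* Sources are processed in blocks of 256 to bound the memory of the flow
  matrix; block boundaries do not change results.
* Deterministic ordering everywhere: vertices iterate in natural id order,
  so reruns are bit-identical.
* Reserves are carried between days keyed on the component's base metamer
  and re-enter as supply located like any component property.

## Problem sizes

The test suite exercises trees of roughly 100–700 metamers (twenty seeds
in the conservation sweep, ≥ 1000 oracle-checked distance pairs across all
five scales); the acceptance script uses a ~2000-metamer tree.  These
sizes were chosen as comfortably representative of young orchard trees
while keeping the full suite in seconds.

## Known limitations

* No interception by intermediate sinks (inherent to the formalism).
* Single-season, fixed structure: no organogenesis, pruning response or
  root architecture; the root system is one opaque compartment.
* The friction parameter is empirical; nothing in the package estimates it
  from data beyond the distribution-comparison utilities.
* Coarse-scale length of branched components is a documented
  approximation (see Distances).
* The tabular interchange format stores at most one intermediate scale
  per file; the native text dialect stores any number.
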