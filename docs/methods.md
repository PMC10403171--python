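# Methods

## The model

`archmatnet` simulates cultural transmission, social interaction and
artifact deposition in a band-structured small-scale society — hunter-
gatherer bands or multi-settlement horticultural communities. Its purpose
is to generate, under controlled conditions, both a *social network* (who
interacted with whom, and how often) and an *archaeological record* (which
artifacts ended up deposited where), so that networks reconstructed from
material culture can be compared with the interaction networks that
produced them.

The world is a square grid partitioned into vertical band territories.
Each band owns exactly three residential camps and one aggregation site at
its territory center; each camp houses a fixed number of people. One tick
represents a month. People carry:

- two cultural **repertoires** — pot traits (stylistic domain) and point
  traits (functional/subsistence domain), each bounded at 10 traits
  (bounded cultural memory, mirroring the object inventories). A trait is
  a `(type, variant)` pair: types are integers, variants the letters a–o.
  Each trait is high- or low-visibility (fair coin at creation). Point
  traits additionally record the environment in which they were
  innovated; they are adaptive there and nowhere else.
- two bounded **inventories** of at most 10 pots and 10 points, each
  object stamped with its creation tick and maker,
- an **alliance** set (mutual ties to members of other camps, trimmed to a
  maximum), and **prestige**: a successful-hunt counter for points, and a
  pottery-prestige value for pots (either random per person, or a single
  randomly flagged person).

Each tick runs eight steps in fixed order:

1. **Environment** — in the mutating mode the single global environment id
   is replaced with a fresh one with probability `pEnvChange`; in the
   zoned mode each band territory keeps its own static environment.
   Alliance sets exceeding `maximumAlliesN` are trimmed at random.
2. **Innovation** — each person may invent a brand-new trait type
   (`pLuckyLeap`), a new variant of a known type (`pNewVariant`), and may
   manufacture one pot and one point (`pNewObject` each) from a random
   repertoire trait, inventory permitting.
3. **Activities** — each band starts aggregating with probability
   `aggregationFreq` for `aggregationDuration` ticks; while aggregated,
   every pair of band members is recorded as visiting each tick, and
   members may still initiate hunts near the aggregation site. People not
   aggregating may form an alliance (`pNewAlliance`), visit a random ally
   (`pVisiting`) — interacting, dropping objects, trading and learning
   with all of their allies present at that camp — or initiate a band
   hunt (`pHunting`) of up to `huntingGroupSize` people, with point drops,
   point trades and point-trait learning among the party.
4. *(consequences of activities happen inline with step 3)*
5. **Loss** — with probability `pLoss` a person forgets one random trait;
   the last trait of a domain can be lost. Loss is the motor of
   between-group differentiation: a full repertoire rejects new traits,
   so only forgetting frees the memory slots through which camp-level
   trait extinction and replacement — and with them cultural drift — can
   proceed. With zero loss a society's culture freezes once memories
   fill, and assemblages stay dominated by the shared starting styles.
6. **Transmission** — each person may learn (`transmissionRate`) from and
   trade (`pTrading`) with co-residents of their current location.
7. **Deposition** — with probabilities `pDropPot`/`pDropPoint` a person
   drops one random object into the current camp's assemblage. Assemblages
   only grow; there is no taphonomy.
8. **Migration** — strictly after `migrationOnsetTick` (default 1000),
   each person may (`pMigration`) swap residence camps with a random
   partner from another camp; with `genderedMigration` both parties must
   belong to the migrating gender. Camp populations are conserved.

Social learning is **prestige-based** (copy a random trait of the most
prestigious co-located person; ties uniform) or **conformist** (adopt the
modal trait of the pool; ties uniform). With the `visibility` switch on, a
visibility class is drawn first — high with probability 0.9 — and if the
class has no candidate traits nothing is transmitted. Learning a genuinely
new trait immediately triggers manufacture of one object of that trait,
inventory permitting. Every realized transmission increments the learning
edge counter, including re-copies of known traits: the counter tracks
interactions, not novel acquisitions.

**Selection on points.** Subsistence tools must work in the local
environment. This is modeled at the transmission stage: when a point trait
is being copied, the choice is restricted (with probability 0.9) to
candidate variants innovated in the learner's current environment whenever
any exist. Hunt success itself is a fair per-hunt coin (p = 0.5, drawn
once per hunt; every participant's prestige increments on success):
coupling success to environmental adaptation instead would make mean point
prestige — one of the 13 output metrics — strongly dependent on the
environmental-change rate, a coupling the model deliberately avoids
because environmental turnover is meant to act (if at all) through
cultural channels, not through the raw activity budget.

## Interaction ledger and migration-safe aggregation

Every hunting, visiting, learning and trading event increments a symmetric
per-pair counter. Because people migrate, each event is *also* tallied
against the camp and band both participants belonged to at event time;
camp/band adjacency tables built from these event-time tallies remain
accurate after migration, unlike tables derived from final membership
(`naive_adjacency`, kept for comparison).

## Output metrics

`metrics_report` computes the 13 summary metrics: assemblage sizes (pots,
points), interaction totals per kind (hunting, learning, trading,
visiting), mean pairwise weighted Jaccard distance between band-pooled and
per-camp assemblages (pots, points), distinct trait counts per domain over
living repertoires, and mean point prestige.

The **weighted Jaccard distance** between count vectors x, y is
1 − Σᵢ min(xᵢ,yᵢ)/Σᵢ max(xᵢ,yᵢ): 0 for identical, 1 for disjoint
assemblages. Band-level distances pool the three camp assemblages per
band before comparison. Pairs of empty assemblages are undefined and
reported as NaN, never as 0.

Additional comparators: **Brainerd–Robinson** similarity on percentage
proportions (200 − Σ|100xᵢ/Σx − 100yᵢ/Σy|, clamped to [0, 200]); an
AMOVA-style **Φst** fixation index over individual repertoires using
binary Jaccard distances and the standard variance-component
decomposition with unequal-group-size correction; Newman weighted
**modularity** of the band partition on the repertoire-similarity graph;
the **clustering gap** (difference of global transitivity between the
interaction network and the material-similarity network, both binarized
at their own median edge weight — the symmetric treatment keeps the
comparison antisymmetric, and the at-least threshold keeps uniformly
weighted graphs intact); median-**binarized edge overlap** (Jaccard of the
two thresholded edge sets, strictly-greater threshold); and Pearson
**edge correlation** over upper-triangle entries.

## The OFAT harness

A sweep varies one parameter over ordered levels, `replicates` runs per
level, seeds `base_seed + level_index*replicates + replicate`. Each
parameter-metric pair is summarized by Spearman's rho (average ranks for
ties), r² = rho², a two-sided p-value, and a 95% CI from the Fisher z
transform with the Bonett–Wright standard error √((1 + ρ²/2)/(n − 3)).
Undefined correlations (constant parameter or metric) are reported as NaN
with a note, never silently dropped or zeroed.

For a balanced two-level sweep in which the two groups' metric values
separate completely, rho equals √3/2 · n/√(n²−1) → 0.866: that is the
ceiling any binary switch can reach and the reference point for the
uniqueTraits result.

## Baseline configuration

The baseline (shipped as `baseline.yaml`, equal to the `ModelConfig`
defaults) represents a three-band society of 90 people observed for 2000
months (~167 years). Monthly event probabilities were chosen once as
ethnographically plausible mid-range values: hunting and visiting ~0.05
per person-month; seasonal aggregations starting with probability 0.02 per
band-month and lasting 5 months (≈ one multi-month aggregation every ~4
years); trade and learning 0.1 per eligible encounter; innovation rare
(new type 0.005, new variant 0.01 per person-month); object manufacture
0.1 per domain per person-month; drop probabilities 0.05; trait loss 0.01
per person-month (a trait is forgotten roughly every 8 years, keeping
cultural turnover slow but nonzero — zero loss suppresses differentiation
entirely); migration 0.002 per person-month (≈ one residential move per
~40 adult years, the order of a post-marital residence change), enabled
after tick 1000 so the first half of the run establishes local tradition.
The mutating environment mode with `pEnvChange = 0.05` is the default so
that the environmental-change parameter is live.

Initial conditions the narration leaves open were fixed as: 5 pot and 5
point traits per person, shared within a camp (so camp-level uniqueness of
starting pools is meaningful); with `uniqueTraits` each camp's starting
type ids are disjoint, otherwise all camps share one pool of styles —
point traits are instantiated per camp so that starting points are
adaptive in the camp's own environment (in the zoned mode this makes
camp pools differ in their environment tag while sharing styles, and the
style-level pools are what "identical" means there). Inventories start
empty and fill within the first few ticks.

## What the generator emulates — and what it does not

Runs emulate the joint accumulation of an interaction network and a
deposited assemblage record under known, controlled dynamics. They do not
model demography (no birth, death or aging — population is constant),
taphonomy or recovery bias (assemblages only grow and are fully observed),
spatial movement cost, or resource budgets. Passing tests therefore show
that the *metrics and harness* behave correctly and that the *simulated*
dynamics reproduce the qualitative sensitivity structure at reduced scale;
they say nothing about how real assemblages sample real interaction.

## Numerical and design choices

- One `random.Random` stream per world; people always processed in id
  order; all draws documented and ordered, so (config, seed) determines
  every output byte-for-byte. Trait sets are sorted deterministically
  before any seeded sampling.
- Ties everywhere (prestige models, modal traits, nearest camps) break
  uniformly at random from the shared stream.
- Trades swap one object of a single kind (with stock on both sides) in
  each direction, so per-kind inventory sizes — and the ≤10 caps — are
  preserved trivially.
- Hunts drop points at the nearest camp of the territory-owning band;
  deposits made while aggregating go to the band camp nearest the
  aggregation site (camps are equidistant from it by construction, so the
  tie-break spreads them uniformly).
- `maximumAlliesN = 0` disables alliance formation outright rather than
  letting transient alliances exist for a tick before trimming.
- Migration partner swaps conserve camp sizes exactly; `migrationOnsetTick`
  is exclusive (first possible migration at tick 1001 with the default).
- Undefined quantities (Jaccard of two empty assemblages, correlation of a
  constant vector, Φst with <2 groups) raise or return NaN explicitly —
  degenerate inputs are surfaced, never coerced to 0.

## Problem sizes used in the shipped analyses

The acceptance analysis and the heavier tests use the baseline scale
(3 bands × 3 camps × 10 people, 2000 ticks) with 20–30 replicates per
sweep level — large enough for the rank statistics to stabilize (the
Monte-Carlo standard error of a null rho at n = 120 is ≈ 0.09) while a
full sweep stays in the minutes range on one core. Unit and property
tests use 2-band, 4-person-camp worlds and exhaustive ≤6-node instances.

## Known limitations

- The between-band Jaccard metric pools each band's camp assemblages
  before comparison (an alternative reading averages camp-pair
  distances); the pooled convention is fixed here and documented.
- The learning counter attributes conformist transmissions to a uniformly
  random holder of the modal trait; the interaction partner is not
  uniquely defined by conformist copying.
- Aggregation-period visiting dominates the visiting totals and carries
  most of their run-to-run variance.
- Categorical parameters (learning method, pottery-prestige mode) enter
  rank correlations by level index; only their two-level sweeps are
  meaningful.
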