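# Methods

## Problem and model

The linker solves within-dataset longitudinal entity resolution for
hospital sites: given annual cohort snapshots, decide for each site in
year *t* which site in year *t+1* (if any) is its continuation. Two key
variables carry the decision — the administrative identification code
(IIC + SC) and the geocoded site location. Both are individually unstable
(codes get renumbered or reassigned, sites relocate), but they rarely
change in the same year; the method exploits that near-complementarity by
scoring each cross-pair with the sum of a code sub-score and a location
sub-score and accepting high-scoring pairs.

The code sub-score is 4 for identical IIC and SC, 2 for identical IIC with
differing SC, and 0 otherwise. SC values are compared after trimming
whitespace and leading zeros ("01" ≡ "1"); an absent SC counts as a
*different* SC, because site identity cannot be confirmed from the IIC
alone — silently equating absent SCs would inflate matches exactly in the
years where SC reporting is weakest. Under `sc_mode="iic_only"` the SC is
ignored entirely (4 for identical IIC), the appropriate regime when a
national SC renumbering makes SCs incomparable between the two years.

The location sub-score is deliberately rank-based rather than
distance-thresholded. From the full pairwise distance matrix, each year-one
site contributes a forward component to its nearest year-two site(s): 2 at
snapped distance zero, 1 at positive distance; the backward direction is
symmetric. Nearest ties are preserved as sets and scored identically. The
sum takes values {0, 1, 2, 4}: a zero-distance pair is necessarily nearest
in both directions, so 2+1=3 cannot occur, and total scores live on
{0, 1, 2, 3, 4, 5, 6, 8} with 7 unattainable. Rank-basedness makes the
score insensitive to the absolute density of sites: "the nearest site in
the same town" is meaningful both in a metropolis and in a rural district.

## Decisions

Candidate pairs at or above the tolerance threshold are accepted greedily
in the order (total descending, distance ascending, lexicographic ids),
subject to one-or-none per facility. The threshold defaults to 1: the
score taxonomy treats any positive similarity as a potential linkage, and
raising the threshold is the analyst's instrument for stricter continuity
definitions (the package only guarantees monotonicity: a higher threshold
never accepts more pairs).

Ties are defined on the total score only. When a facility's best remaining
candidates share the same total and the tie is not already broken by a
competitor's endpoint having been matched elsewhere, all tied pairs go to
a review queue and the facility stays provisionally unlinked; resolution
is external (a CSV of chosen pairs fed back via `resolve_ties` / the CLI
`--resolve` flag). Automated guessing is deliberately refused: the tie
cases are precisely the ones where the two key variables cannot decide,
and any deterministic auto-pick would manufacture confident errors. The
distance and id components of the sort key only make the scan order — and
therefore the outcome — reproducible; they never resolve a score tie.

The city filter runs after selection: an accepted pair whose endpoints lie
in different municipalities (case-folded, punctuation-normalized exact
string comparison) is discarded and both endpoints become unlinked. Freed
facilities are not re-offered their next-best candidate in the same pass;
single-pass semantics keep the decision auditable, at the cost of
occasionally leaving a recoverable pair unlinked (flagged as a known
divergence risk). Pairs with a missing municipality are kept with a
warning, since the filter cannot be evaluated for them.

Continuity types follow from the final link set: 1 constant (linked,
total 8), 2 changed (linked, total < 8), 3 newly opened (year-two site
without linkage), 4 closed (year-one site without linkage). Divisions and
mergers are not first-class outcomes but reconstructed as 2+3 and 2+4;
the division/merge flags record that a facility had two or more
above-threshold candidates before one-or-none selection, leaving the
interpretation of simultaneous flags across transitions to the analyst.

Chaining connects accepted linkages of consecutive transitions into
longitudinal ids of the form `<first year>:<first record id>`. No gap
bridging: a site absent one year restarts under a fresh id, keeping the
panel's opening/closure counts consistent with the pairwise decisions.

## Numerical choices

* Distance: haversine with earth radius 6371.0 km, computed vectorized
  over the full cohort cross-product. Only rank order and exact zeros
  matter downstream, so ellipsoidal refinements would change nothing.
* Zero-distance snapping: distances ≤ `zero_distance_epsilon_m`
  (default 10 m) are set to exactly 0 km before any ranking. 10 m absorbs
  geocoding jitter at the fifth decimal of a degree while keeping distinct
  buildings distinct. With epsilon 0 the comparison degenerates to exact
  coordinate equality.
* Records without coordinates get NaN distances, empty nearest sets and
  location components of 0 against every partner; they can still link on
  code evidence alone.
* The similarity matrix stores only pairs with positive totals, built from
  two sparse candidate sources (shared-IIC pairs via an index, nearest-
  neighbor pairs from the argmin sets); the distance matrix itself is
  dense, which is unproblematic up to a few thousand sites per year.

## Synthetic panel generator

The generator emulates the event structure of a national annual hospital
registry. Municipalities are Gaussian clusters (σ = 0.02°, roughly 2 km)
around centers drawn uniformly on a 47–55°N × 6–15°E patch; each site
belongs to one municipality. Per transition, each facility draws one
event: SC change (default rate 0.03), IIC change (0.009), relocation
within the municipality (0.006), closure (0.005), split (0.001), merger
(0.001), else constant; openings arrive at 0.005 of cohort size. The
defaults sit at the magnitudes reported for the German registry
(≈93–98% constant, ≈1–6% SC-only change, ≈0.7–1.1% IIC change, ≈0.4–0.8%
relocation, ≈0.1–1.2% openings/closures). IICs are 9-digit strings; SCs
are 2-digit, switching to 9-digit for every site from
`sc_regime_switch_year` on, which reproduces the tie inflation of a
national SC renumbering. Record ids are re-issued every year, so the gold
matching cannot be recovered from identifiers. `perturb_addresses`
additionally corrupts a sampled fraction of facilities' coordinates by
200–2000 m in one randomly chosen year, emulating single-year address
input errors.

What the generator does *not* emulate: address strings (coordinates are
generated directly), compound events (a facility changes at most one key
variable per transition by default), clinical content, and spatially
correlated municipality shapes. Passing tests therefore demonstrate that
the pipeline's logic is correct under the stated event model, not that a
particular real registry's idiosyncrasies (consistently mis-geocoded
addresses, simultaneous code-and-location changes, reporting gaps) are
handled; those surface in the review queue and validation diagnostics
rather than being silently absorbed.

Problem sizes in the test suite are chosen for fast feedback: full-recovery
and stress scenarios run at 1,000 facilities over 2–5 years, property
checks at up to 20×20, which already exercises every code path including
ties and conflicts.

## Known limitations

* Greedy selection maximizes locally, not globally; in rare conflict
  constellations an optimal assignment would accept a larger total-score
  sum. The test suite bounds the greedy result by the exhaustive optimum
  on small instances.
* The city filter depends on municipality strings being comparable across
  years; renamed or merged municipalities produce false rejections.
* Facilities freed by the city filter are not re-matched (see above).
* Gold standards are synthetic or user-provided; no manual web-based
  verification workflow is included.
* No fuzzy name matching: descriptive attributes (name, ownership, beds)
  are carried for profiling and review only, never scored.
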