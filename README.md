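# hospilink

Longitudinal linkage of annual hospital-site cohorts.

Hospital registries are published as yearly snapshots: every reporting year
lists the sites active in that year, identified by an administrative code —
an institution identification code (IIC), optionally refined by a site code
(SC) — plus an address. Longitudinal studies (volume–outcome analyses,
minimum-caseload monitoring, market-structure research) need to follow
*the same site* across years, but neither code nor address is stable:
site codes get renumbered (in Germany, nationally between 2019 and 2020),
institutions change owners and therefore IICs, and hospitals relocate
within their city. Linking on identical codes alone silently drops exactly
the sites that changed.

`hospilink` implements a similarity-matrix linker over two key variables,
codes and location, with a synthetic-panel generator so the whole pipeline
can be exercised and validated without access to restricted registry data.

## Method

For every cross-pair (A, B) of a year-one and a year-two cohort, the total
similarity score is the sum of two sub-scores:

**Code sub-score** ∈ {0, 2, 4}

| comparison                      | score |
|---------------------------------|-------|
| identical IIC and SC            | 4     |
| identical IIC, different SC     | 2     |
| different IIC                   | 0     |

**Location sub-score** ∈ {0, 1, 2, 4} — rank-based, from the haversine
distance matrix between the cohorts. The forward component is 2 if B is
A's nearest year-two site at distance zero, 1 if nearest at positive
distance, else 0; the backward component is symmetric (nearest year-one
site of B). Distance zero forces mutual nearest, so the sum 3 is
unattainable; mutually-nearest moved pairs score 2, one-way-nearest pairs
score 1.

Totals live on {0, 1, 2, 3, 4, 5, 6, 8}; 8 means no change in either key
variable. Linkage decisions are one-or-none per facility: candidates at or
above a tolerance threshold (default 1) are accepted greedily by
descending total; ties on the top score are never auto-resolved but queued
for manual review, and accepted linkages that cross a city/town boundary
are discarded. Each facility is then typed: constant (linked, total 8),
changed (linked, total < 8), newly opened (year-two, unlinked) or closed
(year-one, unlinked), with division/merge flags from pre-selection
candidate multiplicity. Pairwise decisions chain into a multi-year panel
with stable longitudinal ids.

## Worked example

Simulate one year-to-year transition of 1,000 sites in which 5% of sites
get a new SC (plus small default rates of IIC change, relocation, closure
and opening), then link it and compare against the code-only baseline:

```python
from hospilink import (SimulationConfig, generate_panel, link_cohorts,
                       baseline_code_linker, score_against_gold)

sim = SimulationConfig(n_facilities=1000, n_years=2, p_sc_change=0.05, seed=11)
panel = generate_panel(sim)
c1, c2 = panel.cohorts
gold = panel.golds[0]

sm, links, continuity = link_cohorts(c1, c2)
print(f"candidate pairs scored : {len(sm)}")
print(f"accepted linkages      : {len(links.accepted)}")
print(f"continuity types       : {continuity.counts()}")

full = score_against_gold(links, gold)
base = score_against_gold(baseline_code_linker(c1, c2), gold)
print(f"similarity method      : {full.true_rate:.1f}% success, {full.missed_matches} missed")
print(f"code-only baseline     : {base.true_rate:.1f}% success, {base.missed_matches} missed")
```

Output:

```
candidate pairs scored : 1016
accepted linkages      : 993
continuity types       : {1: 1876, 2: 110, 3: 5, 4: 7}
similarity method      : 100.0% success, 0 missed
code-only baseline     : 95.1% success, 49 missed
```

Of 2,000 facility-year rows, 1,876 belong to constant sites (total 8) and
110 to sites that changed a code or moved but were still linked; 5 sites
opened and 7 closed. The similarity method recovers every ground-truth
pair, while linking on identical codes alone misses the 49 surviving pairs
whose codes changed — the failure mode that makes code-only linkage
unreliable around a site-code renumbering.

The same workflow is available from the shell:

```
hospilink simulate --n-facilities 1000 --p-sc-change 0.05 --seed 11 --out sim/
hospilink link --cohort 2016=sim/cohort_2016.csv --cohort 2017=sim/cohort_2017.csv --out run/
hospilink evaluate --links run/linkages_2016_2017.csv --gold sim/gold_2016_2017.csv
```

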