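# peonychill

Chilling-requirement (CR) analysis for bud dormancy studies in
perennials, built around the winter biology of herbaceous peony
(*Paeonia lactiflora*) grown under warm subtropical winters.  The
package quantifies how much winter cold a plant's renewal buds need
before dormancy releases, brackets that requirement from chilling
experiments, locates the calendar period in which a given winter
satisfies it, and screens candidate genes whose expression shifts track
that period across winters.

It is a library first: the importable API plus the narrative scripts in
`examples/` are the main interface, with a thin `peonychill` command for
shell use.

## What it computes

**Chill dose models.**  Hourly air temperatures are weighted and summed
over a half-open window [start, end):

- *Chill hours* (CH): weight 1 when 0 °C ≤ T ≤ 7.2 °C (endpoints
  included), else 0.
- *Chill units* (CU): weight 1 for T < 0 °C, `−0.0605·T + 1` for
  0 ≤ T ≤ 10 °C, and 0 above 10 °C.

Refrigerated storage at constant temperature uses the closed form
`hours × weight(T)`; e.g. 35 days at 2 °C gives
`840 × 0.879 = 738.36 CU`.  The start of natural-chill accounting is the
first date whose daily mean stays below a threshold (7.2 °C for CH,
10 °C for CU) for a persistence window of days.

**CR brackets.**  A dose-ladder experiment (transfer dates or storage
durations) plus per-treatment morphology gives an interval estimate:
the CR lies in `(max inadequate dose, min adequate dose]`, with adequacy
decided by configurable thresholds (default: final budbreak ≥ 95 % and
at least one opening flower).  Brackets from independent experiments in
the same unit intersect; for the study's published doses the two CH
brackets intersect at (504.00, 672.00] CH while the CU brackets are
disjoint.

**Reverse use.**  Given the CR, the first sampling checkpoint whose
accumulated chill reaches it dates the CR-fulfillment period; two
winters compare by the calendar delay between their fulfillment dates
(reported in days and whole weeks).

**Candidate-gene screening and congruence.**  From a gene × checkpoint
FPKM matrix with homology annotations: a fold-change screen (with
pseudocount), case-insensitive keyword classification into temperature-
vs photoperiod-associated candidates, per-homolog bookkeeping, and
row z-scoring (population sd, clipped to ±3) for heatmaps.  qPCR Ct
tables aggregate by the 2^−ΔCt method against an in-sample reference
gene.  Finally, a lagged Pearson scan across two winters' six-point
profiles classifies each gene (shifted-similar / partially similar /
dissimilar) and flags genes whose expression shift matches the
CR-fulfillment delay to within one checkpoint interval ("CR-congruent",
the pattern shown by the *SOC1* and *WRKY33* homologs).

A seeded synthetic-data module (`peonychill.synthetic_data`) generates
winters (seasonal + diurnal cosines + AR(1) noise), dose-responsive
morphology with a planted true CR, and paired-winter expression/qPCR
data with a planted lag, so every stage is testable end to end without
downloads.

## Worked example

```
$ python examples/03_fulfillment_reverse_use.py
2012-2013: checkpoints [0, 103, 307, 795, 949, 1227] CH -> CR of 672 CH first met on Jan 21
2015-2016: checkpoints [33, 161, 268, 599, 857, 1084] CH -> CR of 672 CH first met on Feb 04
fulfillment delayed by 14 days = 2 weeks in the warmer winter
```

Each list is one winter's cumulative chilling hours at the six bud
sampling dates (late November through late February).  In the colder
winter the 672-CH optimal requirement is first exceeded at the Jan 21
checkpoint (795 CH); in the warmer winter not until Feb 4 (857 CH) —
dormancy-release conditions arrived two weeks (one sampling interval)
later.  The other examples walk through chill accumulation, bracket
estimation from a simulated dose ladder, expression screening, qPCR
aggregation and the congruence analysis, each printing the numbers it
computes.

A subcommand CLI mirrors the stages:

```
peonychill simulate-winter --seed 1 --out winter.csv
peonychill accumulate --temps winter.csv --model CH --end 2013-01-21
peonychill run-all --seed 0 --output-dir run/
```

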