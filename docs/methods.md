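# Methods

## Detection-calling model

The unit of analysis is the *tally*: the summed read count for one
(sample, primer, taxon) combination in one sequencing run. Runs multiplexed
on patterned flow cells contain a long tail of low-count tallies produced by
index hopping and barcode-region sequencing error; because hops are
approximately random across samples, their per-combination counts are small
relative to genuine amplification signal. The calling rule removes the tail
by *cumulative read mass*, not by a fixed count: with total classified reads
`N` and budget fractions `f_drop ≤ f_low`, the cutoffs are the largest tally
values whose cumulative read sums stay within `f_drop·N` and `f_low·N`
respectively. Tallies at or below the first cutoff are non-detections;
between the cutoffs, low detections requiring validation; above, positive
detections.

Properties guaranteed by construction and asserted at run time:

* both read budgets hold (`Σ reads(not_detected) ≤ f_drop·N`, likewise for
  `not_detected ∪ low` under `f_low`);
* classification is by value — equal read sums always share a category, so
  results are independent of row order and sort stability;
* `cutoff_drop ≤ cutoff_low`, and `cutoff_drop` is non-decreasing in
  `f_drop`.

Cutoffs are stored as the last *dropped* value; the first kept value is the
next distinct tally above. Defaults `f_drop = 0.006` (the lowest published
single-i7 hop rate) and `f_low = 0.010` (bounding plausible single-index swap
mass; dual-index double-swap corrections are unnecessary for single-barcode
chemistry) are configurable because barcode count, depth, and run quality all
reshape the tail, so the fractions are run-tailored settings rather than
constants.

Cutoffs are computed once per run over all field tallies. Control samples
are excluded from the thresholding distribution by default — positive
controls carry deliberately huge counts that would inflate `N` and push the
cutoffs up — but are classified under the resulting cutoffs like any other
sample. A single pooled distribution per run is used (no per-lane split).

## Synthetic run generator

The simulator emulates the statistical structure the thresholds rely on, not
sequencing itself (no reads, quality scores, chimeras, or PCR bias):

* **Design**: sites with water-body types (river/lake/reservoir), ordered
  biweekly events, six replicate 500-mL samples per site visit, plates of 48
  samples carrying one positive and one negative control each. The default
  campaign mirrors a six-water-body season (3 rivers, 2 lakes, 1 reservoir,
  10 events); the benchmark run used in the evaluation is 2 sites × 4 events
  × 6 replicates = 48 field samples with a 30-taxon panel over 10 primers.
* **Signal**: each occupied (site, taxon, primer) is detected in a given
  replicate with probability `p` (default 0.8); a detection draws
  `round(exp(N(μ, σ)))` reads, min 1, with `exp(μ) = 5000` and `σ = 1` by
  default. The log-normal is a stand-in — no count distribution is
  established for this assay class — chosen for its heavy right tail and
  strictly positive support; its parameters are exposed.
* **Index hopping**: each read independently moves with probability `r`
  (default 0.006, admissible range 0–0.06 per published platform estimates)
  to a uniformly chosen *different* sample, keeping primer and taxon —
  single-index hopping on a shared plate. Implemented as binomial thinning
  per source tally with multinomial destinations, recorded in a ledger at
  batch granularity; read totals are conserved exactly.
* **Controls**: positive controls receive the count model for each expected
  mock-community taxon (34 species in the default panel definition) on every
  primer targeting it; negative controls receive nothing directly and can
  gain reads only through the hop mechanism — which is exactly what their QC
  checks.
* **Seasonality**: availability schedules multiply `p` per event, keyed by
  water-body type with optional per-taxon overrides, letting scenarios place
  detection peaks early (river archetype), mid-season (reservoir), or late
  (lake).

Randomness: one global seed; every draw comes from a substream keyed by
(seed, stage, sample, primer, taxon) via hashed seed sequences, so enlarging
the design does not perturb existing draws, and equal seeds give
byte-identical outputs. Hop counts are drawn by inverse CDF on a
rate-independent uniform, so runs sharing a seed are monotonically coupled
across swap rates — the paired-seed sweep comparisons are true couplings.

What passing tests on this generator do **not** show about real data: field
tallies have taxon- and temperature-dependent shedding/decay, spatially
patchy eDNA, primer-efficiency differences, and lane effects, none of which
are modelled; swap artifacts here are exactly uniform, whereas real hopping
has plate-geometry structure. The generator demonstrates that the rule
removes a uniform low-count hop tail at the published rates while retaining
well-separated signal — not that 0.6%/1.0% are optimal for any particular
real run.

## Rank assignment

A didactic single-best-hit classifier preserving the threshold semantics of
the full consensus pipeline: global alignment with match +1, mismatch 0, and
gap columns counted as mismatched columns; identity = matches / alignment
columns, ties among maximum-match alignments resolved toward fewest gap
columns (implemented as an epsilon gap penalty below any match trade-off).
Ranks assign inclusively at the tuned identity thresholds (species 97.8,
genus 96.2, family 88.3, order 81.21, class 80.91); equality attains the
rank, since the thresholds are reported as attained settings. Ties between
references at equal identity go to the lexicographically first reference id.
Ambiguity codes match only on exact character equality. No k-mer search,
LCA, or consensus building.

## Management framework

Categories map to action sets: not_detected → continue screening; low →
re-sample eDNA + traditional survey; positive/confirmed → expand screening
sites + traditional survey + notify agencies + add to tracking + containment
and eradication planning. Histories escalate monotonically: any positive or
any survey confirmation confirms; ≥ 2 low detections across distinct events
(the count is configurable — no canonical number exists) confirms; a lone low
stays low unless an explicit `followup_negative` campaign flag (repeat eDNA
and targeted traditional surveys all negative) returns it to not-observed
status. The follow-up surveys themselves are out of scope; only their boolean
outcome enters.

## Evaluation

Every field combination carrying reads before or after hopping is scored
against the planted truth: *true* if its (site, taxon, primer) is in the
planted occupancy, else *swap-only*. Rates are per combination (management
acts on combinations, not reads): false-positive rate = swap-only
combinations called positive; mediation rate = swap-only held at
not_detected/low; retention = true combinations not removed by the drop
cutoff. Retention is defined against the drop cutoff because the low cutoff
depends only on `f_low` and would make drop-fraction comparisons vacuous.
Note the site-level truth definition counts hop arrivals inside occupied
sites as "true" even in replicates where detection failed; the stricter
per-replicate planted-tally checks are made directly against the simulator's
pre-swap counts. Sweeps reuse one simulation per (rep, rate) across all
fraction cells and pair seeds across rates.

Problem sizes: the test suite and acceptance script use the 48-sample
benchmark (≈ 2 500 tallies, ≈ 10⁷ simulated reads per run), 10–20 seeded
replicates for recovery statistics, and a 4 × 3 rate × fraction grid with 3
replicates — sizes at which the recovery rates are stable to well under a
percentage point while the whole analysis runs in seconds.

## Numerical and degenerate-input choices

* All-zero tally populations are rejected (no classified reads → no tail).
* A run whose smallest tally already exceeds the budget gets cutoffs (0, 0):
  everything is positive, nothing is removed.
* Zero-read tallies are always not_detected; they carry no budget mass.
* Cumulative masses are integer sums compared against float budgets; no
  rounding is applied to the budgets.
* Tables are written in one canonical sort order, so equal inputs produce
  byte-identical files.

## Known limitations

* The simulator's uniform hop destination ignores plate geometry and
  lane structure.
* The rank assigner's alignment is exact but quadratic; it is meant for toy
  reference panels, not genome-scale databases.
* Occupancy modelling of detection probabilities (a natural next layer over
  the replicate profiles) is deliberately not included.
* Threshold fractions are global per run; per-primer or per-plate tailoring
  is not implemented.
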