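# ednadetect

Detection calling and index-swap mediation for **multi-species eDNA
metabarcoding screens** of aquatic invasive species.

Monitoring programs screen large water bodies (rivers, lakes, reservoirs) by
filtering replicate water samples, amplifying dozens of barcoded loci on a
multiplexed plate, sequencing, and tallying classified reads per
(sample, primer, taxon). On patterned flow cells a fraction of reads —
roughly 0.2–6% depending on chemistry — hops to the wrong sample index
("barcode swapping"), scattering spurious low-count taxon records across
samples. Managers then face the core interpretive problem this package
addresses: *where does trace eDNA signal end and index swapping begin*, and
what action should a given detection trigger?

## The method

Let `T = {t₁, t₂, …}` be a run's tallies (read sums per sample × primer ×
taxon combination) and `N = Σ tᵢ` the total classified reads. For budget
fractions `f_drop = 0.006` and `f_low = 0.010`:

* `c_drop` = the largest value `v` with `Σ{tᵢ : tᵢ ≤ v} ≤ f_drop · N`
* `c_low` = the largest value `v` with `Σ{tᵢ : tᵢ ≤ v} ≤ f_low · N`

A tally `t` is **not_detected** if `t ≤ c_drop` (attributed to swaps and
removed), **low** if `c_drop < t ≤ c_low` (requires validation by re-sampling
and traditional survey), and **positive** if `t > c_low` (presumptive
presence: expand screening, notify agencies, add to tracking, begin
containment planning). 0.6% is the lowest published single-i7 swap rate; 1.0%
bounds the plausible swap mass for single-indexed libraries. Classification
is by value, so equal read sums always share a fate, and both read budgets
hold by construction.

Around this rule the package provides:

* a **synthetic multiplexed-run simulator** with planted occupancy,
  log-normal positive counts, per-read binomial index hopping with an exact
  swap ledger, plate positive/negative controls, and seasonal availability
  schedules;
* a simplified **percent-identity rank assigner** (species 97.8 / genus 96.2
  / family 88.3 / order 81.21 / class 80.91, inclusive boundaries);
* the **management framework**: category → action mapping, escalation of
  repeated low detections or survey confirmations, negative-follow-up
  clearance, and plate-control QC;
* **summaries**: replicate detection profiles, season-wide site × species
  matrices, cumulative detection curves and peak-event timing per water-body
  type;
* an **evaluation** harness measuring swap-artifact removal and true-signal
  retention across swap rates and threshold fractions.

## Worked example

```python
from ednadetect import compute_tail_cutoffs, classify_run, study_design, simulate_run

ts = compute_tail_cutoffs([1, 2, 3, 14, 80, 300, 9600])
print(ts.cutoff_drop, ts.cutoff_low)   # 14 80
```

With `N = 10000`, the drop budget is 60 reads: tallies ≤ 14 sum to 20 (adding
the 80-read tally would reach 100 > 60), so `c_drop = 14`; the low budget is
100, met exactly at `c_low = 80`. Four tallies are removed, the 80-read tally
is a low detection, and 300/9600 are positive.

The numbered drivers under `analysis/` run the same machinery at benchmark
scale. `python analysis/01_simulate_run.py` then `02_classify_detections.py`
prints, for the seed-1 benchmark run (48 field samples, 30 taxa × 10 primers,
0.6% swap rate):

```
simulated 2496 tallies, 10585777 reads total
63637 reads hopped between samples (0.60% of the run)
total classified reads 9883506; cutoffs: drop <= 972, low <= 1204
categories: {'not_detected': 1253, 'positive': 1204, 'low': 39}
negative-control contamination flags: 0
positive control plate01-pos: 30/30 expected taxa recovered, missing []
```

The 1253 removed combinations are almost entirely hop artifacts (the planted
signal sits near 5000 reads per tally), the removed read mass is ≈ 0.6% of
the run by construction, and the clean negative controls confirm the
artifacts came from hopping, not contamination. `03_summarize_season.py` and
`04_threshold_sweep.py` add the seasonal curves (peak events river = 1,
reservoir = 5, lake = 9 under early/mid/late availability) and the
swap-rate × drop-fraction sweep.

The same steps are available as a console tool (`ednadetect simulate`,
`classify`, `classify-seqs`, `summarize`, `recommend`, `evaluate`, `run`);
`ednadetect run --config cfg.yaml` executes the whole pipeline and stamps
every bundle with a provenance JSON carrying the fractions used.

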