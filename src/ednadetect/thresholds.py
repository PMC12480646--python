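"""Cumulative-tail read-count thresholds and three-way detection calling.

Multiplexed amplicon runs on patterned flow cells mis-assign a small fraction
of reads to the wrong sample index ("index hopping" / barcode swapping). Those
reads scatter roughly uniformly across samples, so in a tally table — reads
summed per (sample, primer, taxon) — they appear as a long tail of low-count
combinations. The mediation rule used here removes the smallest tallies whose
*cumulative read mass* stays within a budget expressed as a fraction of the
total classified reads in the run:

* ``drop_frac`` (default 0.006, the lowest published single-i7 swap rate):
  tallies at or below ``cutoff_drop`` are ``not_detected`` and removed.
* ``low_frac`` (default 0.010, covering the plausible swap range for
  single-indexed libraries): tallies above ``cutoff_drop`` but at or below
  ``cutoff_low`` are ``low`` detections that require validation before any
  management response.
* Everything above ``cutoff_low`` is a ``positive`` detection.

``cutoff_drop`` is the largest tally value ``v`` such that the summed reads of
all tallies ``<= v`` do not exceed ``drop_frac * total``; ``cutoff_low`` is
defined analogously with ``low_frac``. Classification is by value, so equal
read-sums always share a fate regardless of row order. Both cutoffs are stored
as the last *dropped* value (the first kept value is the next distinct tally
above them).

Cutoff fractions are run-level tuning knobs: sequencing depth, barcode count
and run quality all shape the tail, so the defaults may need tailoring to a
given dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .io import TALLY_COLUMNS, sort_table


class ThresholdConfig(BaseModel):
    """Fractional read budgets for the non-detection and low-detection tails."""

    drop_frac: float = Field(default=0.006, ge=0.0, lt=1.0)
    low_frac: float = Field(default=0.010, ge=0.0, lt=1.0)
    include_controls_in_distribution: bool = False

    @model_validator(mode="after")
    def _ordered(self) -> "ThresholdConfig":
        if self.drop_frac > self.low_frac:
            raise ValueError(
                f"drop_frac ({self.drop_frac}) must not exceed low_frac ({self.low_frac})"
            )
        return self


@dataclass(frozen=True)
class ThresholdSet:
    """Read-sum cutoffs derived from one run's tally distribution."""

    total_reads: int
    cutoff_drop: int
    cutoff_low: int
    drop_frac: float
    low_frac: float

    def to_dict(self) -> dict:
        return asdict(self)


def compute_tail_cutoffs(read_sums, config: ThresholdConfig | None = None) -> ThresholdSet:
    """Derive the (cutoff_drop, cutoff_low) pair from a multiset of tally read-sums.

    Parameters
    ----------
    read_sums
        Array-like of nonnegative integer tallies (the per-combination read
        sums of one run); zeros are allowed and carry no mass.
    config
        Fractional budgets; defaults to 0.6% / 1.0%.

    Raises
    ------
    ValueError
        If no tally is positive (a run with no classified reads has no tail).
    """
    config = config or ThresholdConfig()
    vals = np.asarray(read_sums)
    if vals.size == 0 or not np.issubdtype(vals.dtype, np.number):
        raise ValueError("read_sums must be a nonempty numeric collection")
    if (vals < 0).any():
        raise ValueError("read_sums must be nonnegative")
    vals = vals[vals > 0].astype(np.int64)
    if vals.size == 0:
        raise ValueError("no classified reads: all tallies are zero")

    uniq, counts = np.unique(vals, return_counts=True)
    mass = np.cumsum(uniq * counts)  # reads in tallies <= uniq[i]
    total = int(mass[-1])

    def largest_within(budget: float) -> int:
        k = int(np.searchsorted(mass, budget, side="right"))
        return int(uniq[k - 1]) if k > 0 else 0

    cutoff_drop = largest_within(config.drop_frac * total)
    cutoff_low = largest_within(config.low_frac * total)
    ts = ThresholdSet(
        total_reads=total,
        cutoff_drop=cutoff_drop,
        cutoff_low=cutoff_low,
        drop_frac=config.drop_frac,
        low_frac=config.low_frac,
    )
    # Budget bounds hold by construction; keep them as hard guarantees.
    dropped = int(vals[vals <= cutoff_drop].sum())
    low_or_less = int(vals[vals <= cutoff_low].sum())
    assert dropped <= config.drop_frac * total + 1e-9
    assert low_or_less <= config.low_frac * total + 1e-9
    assert 0 <= cutoff_drop <= cutoff_low
    return ts


def classify_tally(read_sum: int, thresholds: ThresholdSet) -> str:
    """Category of a single tally under a fixed ThresholdSet."""
    if read_sum < 0:
        raise ValueError("read_sum must be >= 0")
    if read_sum <= thresholds.cutoff_drop:
        return "not_detected"
    if read_sum <= thresholds.cutoff_low:
        return "low"
    return "positive"


def classify_run(
    tallies: pd.DataFrame,
    manifest,
    config: ThresholdConfig | None = None,
) -> tuple[ThresholdSet, pd.DataFrame]:
    """Compute run-level cutoffs and classify every tally of the run.

    Cutoffs are derived once from the configured tally population — control
    samples are excluded by default so that the deliberately large
    positive-control counts do not inflate the total — and then applied to
    every row, controls included. The returned detection table partitions the
    input: every tally appears exactly once with a category.
    """
    config = config or ThresholdConfig()
    if tallies.empty:
        raise ValueError("empty tally table")
    ctl = set(manifest.control_ids())
    if config.include_controls_in_distribution:
        population = tallies["reads"]
    else:
        population = tallies.loc[~tallies["sample_id"].isin(ctl), "reads"]
    ts = compute_tail_cutoffs(population, config)

    out = tallies[TALLY_COLUMNS].copy()
    reads = out["reads"].to_numpy()
    out["category"] = np.select(
        [reads <= ts.cutoff_drop, reads <= ts.cutoff_low],
        ["not_detected", "low"],
        default="positive",
    )
    out["threshold_run_id"] = manifest.run_id
    return ts, sort_table(out)
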