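"""Simulation study of the tail-threshold mediation rule.

Scores each simulated run exactly against its ground truth: every field
(sample, primer, taxon) combination that carries reads (before or after
swapping) is either *true* — its (site, taxon, primer) belongs to the planted
occupancy — or *swap-only*, an artifact created entirely by index hopping.
Specificity is how many swap-only combinations the thresholds remove or hold
at the low tier; sensitivity is how many true combinations survive. Sweeps
over swap rate and threshold fractions reuse one simulation per (rep, rate)
and share per-rep seeds across grid cells, and the simulator's inverse-CDF
swap draws make those paired runs monotonically coupled in the swap rate.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

from .io import RunManifest
from .simulate import SimParams, TrueState, add_controls, simulate_run
from .thresholds import ThresholdConfig, ThresholdSet, classify_run


@dataclass(frozen=True)
class EvalResult:
    """Per-run confusion counts over combinations, plus the derived rates."""

    swap_rate: float
    drop_frac: float
    low_frac: float
    seed: int
    n_swap_combos: int
    n_swap_removed: int
    n_swap_low: int
    n_swap_positive: int
    n_true_combos: int
    n_true_removed: int
    n_true_low: int
    n_true_positive: int
    cutoff_drop: int
    cutoff_low: int
    total_reads: int

    def __post_init__(self) -> None:
        assert self.n_swap_removed + self.n_swap_low + self.n_swap_positive == self.n_swap_combos
        assert self.n_true_removed + self.n_true_low + self.n_true_positive == self.n_true_combos

    @property
    def swap_fp_rate(self) -> float:
        """Fraction of swap-only combinations that classified positive (0 if none)."""
        if self.n_swap_combos == 0:
            return 0.0
        return self.n_swap_positive / self.n_swap_combos

    @property
    def swap_mediation_rate(self) -> float:
        """Fraction of swap-only combinations held at not_detected or low."""
        if self.n_swap_combos == 0:
            return 1.0
        return (self.n_swap_removed + self.n_swap_low) / self.n_swap_combos

    @property
    def true_retention(self) -> float:
        """Fraction of true combinations not removed by the drop cutoff."""
        if self.n_true_combos == 0:
            return 1.0
        return 1.0 - self.n_true_removed / self.n_true_combos

    @property
    def true_positive_rate(self) -> float:
        if self.n_true_combos == 0:
            return 1.0
        return self.n_true_positive / self.n_true_combos

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(
            swap_fp_rate=self.swap_fp_rate,
            swap_mediation_rate=self.swap_mediation_rate,
            true_retention=self.true_retention,
            true_positive_rate=self.true_positive_rate,
        )
        return d


def score_run(
    truth: TrueState,
    detections: pd.DataFrame,
    thresholds: ThresholdSet,
    manifest: RunManifest,
    params: SimParams,
) -> EvalResult:
    """Exact confusion counts for one classified run against its ground truth.

    The scored universe is every field combination with pre-swap reads plus
    every field combination appearing in the post-swap table; a combination
    absent from the table (all reads swapped away) counts as not_detected.
    Controls are excluded — their QC lives in the framework module.
    """
    ctl = set(manifest.control_ids())
    cat = {
        (r.sample_id, r.primer_id, r.taxon): r.category
        for r in detections.itertuples(index=False)
        if r.sample_id not in ctl
    }
    universe = set(truth.pre_swap) | set(cat)
    counts = {("swap", c): 0 for c in ("not_detected", "low", "positive")}
    counts.update({("true", c): 0 for c in ("not_detected", "low", "positive")})
    for key in universe:
        sid, primer, taxon = key
        parsed = RunManifest.parse_sample_id(sid)
        site = parsed[0] if parsed else None
        is_true = (site, taxon, primer) in truth.occupancy
        category = cat.get(key, "not_detected")
        counts[("true" if is_true else "swap", category)] += 1
    return EvalResult(
        swap_rate=params.swap_rate,
        drop_frac=thresholds.drop_frac,
        low_frac=thresholds.low_frac,
        seed=params.seed,
        n_swap_combos=sum(counts[("swap", c)] for c in ("not_detected", "low", "positive")),
        n_swap_removed=counts[("swap", "not_detected")],
        n_swap_low=counts[("swap", "low")],
        n_swap_positive=counts[("swap", "positive")],
        n_true_combos=sum(counts[("true", c)] for c in ("not_detected", "low", "positive")),
        n_true_removed=counts[("true", "not_detected")],
        n_true_low=counts[("true", "low")],
        n_true_positive=counts[("true", "positive")],
        cutoff_drop=thresholds.cutoff_drop,
        cutoff_low=thresholds.cutoff_low,
        total_reads=thresholds.total_reads,
    )


def evaluate_once(
    manifest: RunManifest,
    params: SimParams,
    config: ThresholdConfig | None = None,
    with_controls: bool = True,
) -> tuple[EvalResult, TrueState, pd.DataFrame]:
    """Simulate one run, classify it, and score recovery against the truth."""
    config = config or ThresholdConfig()
    truth, tallies = simulate_run(manifest, params)
    if with_controls and any(c.kind == "positive" and c.expected_taxa for c in manifest.controls):
        tallies, truth = add_controls(tallies, manifest, params, truth)
    thresholds, detections = classify_run(tallies, manifest, config)
    return score_run(truth, detections, thresholds, manifest, params), truth, detections


def sweep(
    manifest: RunManifest,
    base_params: SimParams,
    swap_rates: list[float],
    drop_fracs: list[float],
    low_frac: float = 0.010,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Grid sweep over swap rates × drop fractions with paired per-rep seeds.

    One simulation per (rep, swap_rate) is classified under every drop_frac,
    so comparisons across fractions share the identical tally table and
    comparisons across rates share coupled random draws. Returns one row per
    grid cell per rep with all confusion counts and rates.
    """
    if not swap_rates or not drop_fracs:
        raise ValueError("empty sweep grid")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for rep in range(n_reps):
        rep_seed = (seed + 7919 * rep) % (2**31)
        for rate in swap_rates:
            params = base_params.model_copy(update={"swap_rate": rate, "seed": rep_seed})
            truth, tallies = simulate_run(manifest, params)
            for drop in drop_fracs:
                config = ThresholdConfig(drop_frac=drop, low_frac=max(drop, low_frac))
                thresholds, detections = classify_run(tallies, manifest, config)
                result = score_run(truth, detections, thresholds, manifest, params)
                row = result.to_dict()
                row["rep"] = rep
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_sweep(results: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd of the key rates per (swap_rate, drop_frac, low_frac) cell."""
    rates = ["swap_fp_rate", "swap_mediation_rate", "true_retention", "true_positive_rate"]
    grouped = results.groupby(["swap_rate", "drop_frac", "low_frac"])[rates]
    out = grouped.agg(["mean", "std"])
    out.columns = [f"{a}_{b}" for a, b in out.columns]
    return out.reset_index().fillna(0.0)
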