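"""Synthetic multiplexed metabarcoding runs with planted truth and index swaps.

The generator emulates the statistical structure the tail-threshold analysis
assumes: a body of high-count true detections — each occupied
(site, taxon, primer) yields, per replicate water sample, a positive read
count with probability ``detection_prob``, drawn from a rounded log-normal —
plus a long tail of low-count artifacts created by per-read index swapping.
Each read is independently reassigned, with probability ``swap_rate``, to a
uniformly chosen *different* sample on the run (primer and taxon unchanged),
modelling single-index (i7) hopping on a shared plate. Published platform
swap rates span 0.2–6% of reads, and ``swap_rate`` is bounded accordingly.

Every random draw comes from a substream keyed by (seed, stage, sample,
primer, taxon), so adding sites or taxa does not perturb earlier draws, and
swap thinning uses inverse-CDF sampling on a rate-independent uniform so runs
that share a seed are monotonically coupled across swap rates.

Ground truth (planted occupancy, pre-swap counts, and a ledger of every swap
batch) is returned alongside the tally table so recovery can be scored
exactly. Read totals are conserved by construction: the post-swap tallies sum
to the pre-swap counts.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from pydantic import ValidationError as PydanticValidationError
from scipy.stats import binom

from .io import (
    CONTROL_SITE,
    ControlSample,
    RunManifest,
    SamplingEvent,
    Site,
    field_sample_id,
    tallies_from_records,
)

#: Published per-read swap-rate range for patterned flow cells.
MAX_SWAP_RATE = 0.06

Key = tuple[str, str, str]  # (sample_id, primer_id, taxon)


class ParameterError(ValueError):
    """A simulation parameter is outside its admissible range."""


def _stream(seed: int, *tags) -> np.random.Generator:
    """Deterministic substream keyed by (seed, tags); stable under panel growth."""
    entropy = [seed & 0x7FFFFFFF] + [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence(entropy))


class TaxonSpec(BaseModel):
    """One panel taxon: the primers that amplify it and the sites it occupies."""

    name: str
    primers: list[str] = Field(min_length=1)
    sites: list[str] = Field(default_factory=list)
    rank: str = "species"


class SimParams(BaseModel):
    """Simulation parameters; defaults reflect the study regime the analysis targets.

    ``log_mean``/``log_sd`` parameterize the log-normal positive-count model
    (default exp(log_mean) ≈ 5000 reads, a strong amplicon signal well
    separated from swap fragments); ``swap_rate`` defaults to 0.006, the
    lowest published single-i7 hopping rate.
    """

    taxa: list[TaxonSpec]
    detection_prob: float = Field(default=0.8, ge=0.0, le=1.0)
    log_mean: float = math.log(5000.0)
    log_sd: float = Field(default=1.0, gt=0.0)
    swap_rate: float = Field(default=0.006, ge=0.0)
    control_detection_prob: float = Field(default=1.0, ge=0.0, le=1.0)
    seed: int = 0

    @field_validator("swap_rate")
    @classmethod
    def _rate_in_published_range(cls, v: float) -> float:
        if v > MAX_SWAP_RATE:
            raise ParameterError(
                f"swap_rate {v} exceeds the published platform maximum {MAX_SWAP_RATE}"
            )
        return v

    @model_validator(mode="after")
    def _sites_unique(self) -> "SimParams":
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            raise ParameterError("duplicate taxon names in panel")
        return self


class AvailabilitySchedule(BaseModel):
    """Per-event multipliers on detection probability, keyed by water-body type.

    Encodes seasonal availability: e.g. a river curve peaking at the first
    event versus a lake curve peaking late. ``taxon_curves`` overrides the
    water-body curve for individual taxa.
    """

    n_events: int = Field(ge=1)
    curves: dict[str, list[float]] = Field(default_factory=dict)
    taxon_curves: dict[str, list[float]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _valid(self) -> "AvailabilitySchedule":
        for name, curve in list(self.curves.items()) + list(self.taxon_curves.items()):
            if len(curve) != self.n_events:
                raise ParameterError(
                    f"curve {name!r} has {len(curve)} entries for {self.n_events} events"
                )
            if any(m < 0 for m in curve):
                raise ParameterError(f"curve {name!r} has a negative multiplier")
        return self

    def multiplier(self, water_body_type: str, taxon: str, event_pos: int) -> float:
        """Multiplier for the event at 0-based position ``event_pos``."""
        if taxon in self.taxon_curves:
            return self.taxon_curves[taxon][event_pos]
        if water_body_type in self.curves:
            return self.curves[water_body_type][event_pos]
        return 1.0


def seasonal_scenario(
    manifest: RunManifest,
    params: SimParams,
    curves: dict[str, list[float]],
    taxon_curves: dict[str, list[float]] | None = None,
) -> AvailabilitySchedule:
    """Build a validated event-indexed availability schedule for a run."""
    try:
        return AvailabilitySchedule(
            n_events=len(manifest.events),
            curves=curves,
            taxon_curves=taxon_curves or {},
        )
    except PydanticValidationError as exc:
        first = exc.errors()[0].get("msg", str(exc))
        raise ParameterError(first.removeprefix("Value error, ")) from exc


@dataclass(frozen=True)
class SwapEvent:
    """One batch of reads hopped from a source to a destination sample."""

    n_reads: int
    source: str
    dest: str
    primer_id: str
    taxon: str


@dataclass
class TrueState:
    """Simulator ground truth for recovery scoring.

    ``occupancy`` is the planted site-level truth; ``pre_swap`` holds the
    per-sample counts before any index hopping (field samples), with control
    counts kept separately so field recovery metrics are unambiguous.
    """

    occupancy: set[tuple[str, str, str]] = field(default_factory=set)  # (site, taxon, primer)
    pre_swap: dict[Key, int] = field(default_factory=dict)
    control_pre_swap: dict[Key, int] = field(default_factory=dict)
    ledger: list[SwapEvent] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)

    def total_pre_swap(self) -> int:
        return sum(self.pre_swap.values()) + sum(self.control_pre_swap.values())

    def n_swapped_reads(self) -> int:
        return sum(ev.n_reads for ev in self.ledger)

    def swapped_into(self, sample_id: str) -> list[SwapEvent]:
        return [ev for ev in self.ledger if ev.dest == sample_id]

    # -- JSON round trip (CLI artifact) ---------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "occupancy": sorted(map(list, self.occupancy)),
            "pre_swap": [[*k, v] for k, v in sorted(self.pre_swap.items())],
            "control_pre_swap": [[*k, v] for k, v in sorted(self.control_pre_swap.items())],
            "ledger": [
                [ev.n_reads, ev.source, ev.dest, ev.primer_id, ev.taxon] for ev in self.ledger
            ],
            "samples": self.samples,
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "TrueState":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            occupancy={tuple(t) for t in doc["occupancy"]},
            pre_swap={(s, p, t): n for s, p, t, n in doc["pre_swap"]},
            control_pre_swap={(s, p, t): n for s, p, t, n in doc["control_pre_swap"]},
            ledger=[SwapEvent(n, s, d, p, t) for n, s, d, p, t in doc["ledger"]],
            samples=list(doc["samples"]),
        )


def _draw_count(rng: np.random.Generator, log_mean: float, log_sd: float) -> int:
    return max(1, int(round(math.exp(rng.normal(log_mean, log_sd)))))


def _apply_swaps(
    counts: dict[Key, int],
    all_samples: list[str],
    rate: float,
    seed: int,
    stage: str,
    ledger: list[SwapEvent],
) -> dict[Key, int]:
    """Binomially thin each tally and scatter the hopped reads uniformly.

    Equivalent to per-read reassignment: the number of hopped reads from a
    tally of size c is Binomial(c, rate), drawn by inverse CDF on a uniform
    that does not depend on the rate (monotone coupling across rates), and
    destinations are multinomial-uniform over the other samples of the run.
    """
    post: dict[Key, int] = dict(counts)
    if rate == 0.0 or not counts:
        return post
    sample_index = {s: i for i, s in enumerate(all_samples)}
    n_samp = len(all_samples)
    if n_samp < 2:
        return post
    for (sid, primer, taxon), c in sorted(counts.items()):
        if c == 0:
            continue
        rng = _stream(seed, "swap", stage, sid, primer, taxon)
        u = rng.random()
        n_sw = int(binom.ppf(u, c, rate))
        if n_sw <= 0:
            continue
        others = [s for s in all_samples if s != sid]
        dest_counts = rng.multinomial(n_sw, np.full(len(others), 1.0 / len(others)))
        post[(sid, primer, taxon)] -= n_sw
        for dest, k in zip(others, dest_counts):
            if k == 0:
                continue
            key = (dest, primer, taxon)
            post[key] = post.get(key, 0) + int(k)
            ledger.append(SwapEvent(int(k), sid, dest, primer, taxon))
    return post


def _counts_to_table(
    counts: dict[Key, int],
    manifest: RunManifest,
    rank_of: dict[str, str],
) -> pd.DataFrame:
    records = []
    ctl = set(manifest.control_ids())
    for (sid, primer, taxon), reads in sorted(counts.items()):
        if reads <= 0:
            continue
        if sid in ctl:
            site, event, rep = CONTROL_SITE, 0, 0
        else:
            site, event, rep = RunManifest.parse_sample_id(sid)  # type: ignore[misc]
        records.append(
            dict(
                sample_id=sid,
                site_id=site,
                event_index=event,
                replicate=rep,
                primer_id=primer,
                taxon=taxon,
                rank=rank_of.get(taxon, "species"),
                reads=reads,
            )
        )
    return tallies_from_records(records)


def simulate_run(
    manifest: RunManifest,
    params: SimParams,
    schedule: AvailabilitySchedule | None = None,
) -> tuple[TrueState, pd.DataFrame]:
    """Simulate the field samples of one multiplexed run.

    Returns the ground truth and the post-swap tally table (field reads only;
    use :func:`add_controls` afterwards to place plate controls). Control
    sample ids declared in the manifest are already eligible swap destinations
    here, so a negative control can pick up hopped reads exactly as on a real
    plate.
    """
    if schedule is not None and schedule.n_events != len(manifest.events):
        raise ParameterError("schedule event count disagrees with manifest")
    truth = TrueState(samples=manifest.all_sample_ids())
    event_pos = {e: i for i, e in enumerate(manifest.event_indices())}
    site_ids = {s.site_id for s in manifest.sites}

    for taxon in params.taxa:
        for site in taxon.sites:
            if site not in site_ids:
                raise ParameterError(f"taxon {taxon.name!r} occupies unknown site {site!r}")
            wbt = manifest.water_body_of(site)
            for primer in taxon.primers:
                truth.occupancy.add((site, taxon.name, primer))
                for ev in manifest.event_indices():
                    mult = 1.0 if schedule is None else schedule.multiplier(
                        wbt, taxon.name, event_pos[ev]
                    )
                    p_eff = min(1.0, params.detection_prob * mult)
                    for rep in range(1, manifest.replicates_per_event + 1):
                        sid = field_sample_id(site, ev, rep)
                        rng = _stream(params.seed, "counts", sid, primer, taxon.name)
                        detected = rng.random() < p_eff
                        if detected:
                            c = _draw_count(rng, params.log_mean, params.log_sd)
                            key = (sid, primer, taxon.name)
                            truth.pre_swap[key] = truth.pre_swap.get(key, 0) + c

    post = _apply_swaps(
        truth.pre_swap, truth.samples, params.swap_rate, params.seed, "field", truth.ledger
    )
    rank_of = {t.name: t.rank for t in params.taxa}
    return truth, _counts_to_table(post, manifest, rank_of)


def add_controls(
    tallies: pd.DataFrame,
    manifest: RunManifest,
    params: SimParams,
    truth: TrueState | None = None,
) -> tuple[pd.DataFrame, TrueState]:
    """Add plate-control reads to a simulated tally table.

    Each positive control gains a log-normal count for every expected taxon on
    every primer that targets it (a genomic-DNA mock community); those reads
    are then subject to the same per-read swap mechanism, so a negative
    control acquires reads *only* through the swap ledger.
    """
    if truth is None:
        truth = TrueState(samples=manifest.all_sample_ids())
    primers_of = {t.name: t.primers for t in params.taxa}
    rank_of = {t.name: t.rank for t in params.taxa}

    ctl_counts: dict[Key, int] = {}
    for ctl in manifest.controls:
        if ctl.kind != "positive":
            continue
        if not ctl.expected_taxa:
            raise ValueError(f"positive control {ctl.sample_id} has empty expected_taxa")
        for taxon in ctl.expected_taxa:
            primers = primers_of.get(taxon, [f"{taxon}-assay"])
            for primer in primers:
                rng = _stream(params.seed, "control", ctl.sample_id, primer, taxon)
                if rng.random() < params.control_detection_prob:
                    ctl_counts[(ctl.sample_id, primer, taxon)] = _draw_count(
                        rng, params.log_mean, params.log_sd
                    )
    truth.control_pre_swap.update(ctl_counts)
    post = _apply_swaps(
        ctl_counts, truth.samples, params.swap_rate, params.seed, "control", truth.ledger
    )
    extra = _counts_to_table(post, manifest, rank_of)
    merged = pd.concat([tallies, extra], ignore_index=True)
    key = ["sample_id", "primer_id", "taxon"]
    carried = ["site_id", "event_index", "replicate", "rank"]
    merged = merged.groupby(key + carried, as_index=False, sort=False)["reads"].sum()
    return tallies_from_records(merged.to_dict("records")), truth


# ---------------------------------------------------------------------------
# Design builders: canonical synthetic study layouts
# ---------------------------------------------------------------------------

#: Size of the mock-community positive control (species pooled per plate).
N_CONTROL_TAXA = 34

#: Samples per plate, two of which are the plate's positive/negative controls.
PLATE_SIZE = 48


def make_manifest(
    n_rivers: int = 3,
    n_lakes: int = 2,
    n_reservoirs: int = 1,
    n_events: int = 10,
    replicates: int = 6,
    run_id: str = "synthetic-run",
    control_taxa: list[str] | None = None,
    plate_size: int = PLATE_SIZE,
) -> RunManifest:
    """Build a campaign manifest.

    Defaults mirror a season-long screen of six large water bodies (three
    rivers, two lakes, one reservoir) sampled biweekly for ten events with six
    500-mL replicates per site visit, with one positive and one negative
    control per plate of ``plate_size`` samples.
    """
    sites = (
        [Site(site_id=f"river{i + 1}", water_body_type="river") for i in range(n_rivers)]
        + [Site(site_id=f"lake{i + 1}", water_body_type="lake") for i in range(n_lakes)]
        + [
            Site(site_id=f"reservoir{i + 1}", water_body_type="reservoir")
            for i in range(n_reservoirs)
        ]
    )
    events = [SamplingEvent(event_index=i + 1, label=f"event-{i + 1:02d}") for i in range(n_events)]
    n_field = len(sites) * n_events * replicates
    per_plate_field = plate_size - 2
    n_plates = max(1, -(-n_field // per_plate_field))
    controls = []
    for plate in range(1, n_plates + 1):
        controls.append(
            ControlSample(
                sample_id=f"plate{plate:02d}-pos",
                kind="positive",
                expected_taxa=list(control_taxa) if control_taxa else [],
                plate=plate,
            )
        )
        controls.append(
            ControlSample(sample_id=f"plate{plate:02d}-neg", kind="negative", plate=plate)
        )
    return RunManifest(
        run_id=run_id,
        sites=sites,
        events=events,
        replicates_per_event=replicates,
        controls=controls,
    )


def random_panel(
    manifest: RunManifest,
    n_taxa: int = 30,
    n_primers: int = 10,
    seed: int = 0,
    occupancy_prob: float = 0.5,
    max_primers_per_taxon: int = 2,
) -> list[TaxonSpec]:
    """Random taxon panel: primer targeting and site occupancy with known truth."""
    if not 0.0 <= occupancy_prob <= 1.0:
        raise ParameterError("occupancy_prob must lie in [0, 1]")
    rng = _stream(seed, "panel")
    primers = [f"primer{i + 1:02d}" for i in range(n_primers)]
    sites = [s.site_id for s in manifest.sites]
    taxa = []
    for i in range(n_taxa):
        k = int(rng.integers(1, max_primers_per_taxon + 1))
        chosen = sorted(rng.choice(primers, size=min(k, n_primers), replace=False).tolist())
        occupied = [s for s in sites if rng.random() < occupancy_prob]
        if not occupied:  # keep every taxon informative
            occupied = [sites[int(rng.integers(len(sites)))]]
        taxa.append(TaxonSpec(name=f"taxon{i + 1:02d}", primers=chosen, sites=occupied))
    return taxa


def study_design(
    seed: int = 0,
    n_taxa: int = 30,
    n_primers: int = 10,
    swap_rate: float = 0.006,
) -> tuple[RunManifest, SimParams]:
    """The 48-field-sample benchmark run used throughout the evaluation.

    Two sites (one river, one lake) × four events × six replicates = 48 field
    samples on one plate-pair, a 30-taxon panel over 10 primers, positive
    counts around exp(log_mean) ≈ 5000 reads, and the default 0.6% swap rate.
    """
    manifest = make_manifest(
        n_rivers=1,
        n_lakes=1,
        n_reservoirs=0,
        n_events=4,
        replicates=6,
        run_id=f"bench-seed{seed}",
    )
    taxa = random_panel(manifest, n_taxa=n_taxa, n_primers=n_primers, seed=seed)
    mock_community = [t.name for t in taxa[:N_CONTROL_TAXA]]
    for ctl in manifest.controls:
        if ctl.kind == "positive":
            ctl.expected_taxa = mock_community
    params = SimParams(taxa=taxa, swap_rate=swap_rate, seed=seed)
    return manifest, params
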