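"""Tabular I/O for metabarcoding tally tables, run manifests, and detection tables.

The atomic record is a *tally*: the summed read count for one
(sample, primer, taxon) combination in a sequencing run. Tally tables are
tab-separated with the frozen header::

    sample_id  site_id  event_index  replicate  primer_id  taxon  rank  reads

Run manifests are JSON documents describing the field design (sites and their
water-body types, the ordered biweekly sampling events, the number of replicate
water samples per site visit) plus the positive/negative control samples placed
on each 48-sample plate. Detection tables add ``category`` (one of
``not_detected | low | positive``) and ``threshold_run_id`` columns and are
written as CSV, sorted so that two writes of the same table are byte-identical.

Field samples are identified as ``<site_id>.e<event>.r<replicate>``; control
samples carry their manifest ``sample_id`` and use ``site_id="-"``,
``event_index=0``, ``replicate=0`` in tabular form. Taxon names are opaque
canonical strings — no taxonomy database is consulted.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

TALLY_COLUMNS = [
    "sample_id",
    "site_id",
    "event_index",
    "replicate",
    "primer_id",
    "taxon",
    "rank",
    "reads",
]
DETECTION_COLUMNS = TALLY_COLUMNS + ["category", "threshold_run_id"]

#: Taxonomic ranks a tally may carry, deepest first.
RANKS = ("species", "genus", "family", "order", "class", "unclassified")

#: Detection categories, ordered from weakest to strongest evidence.
CATEGORIES = ("not_detected", "low", "positive")

#: Sort order that makes detection/tally tables byte-stable on disk.
TABLE_SORT = ["site_id", "event_index", "primer_id", "taxon", "replicate", "sample_id"]

CONTROL_SITE = "-"

_ID_RE = re.compile(r"^[A-Za-z0-9_-]+$")
_SAMPLE_RE = re.compile(r"^(?P<site>[A-Za-z0-9_-]+)\.e(?P<event>\d+)\.r(?P<rep>\d+)$")


class SchemaError(ValueError):
    """A table is missing a required column or has the wrong shape."""


class TallyValidationError(ValueError):
    """A table row violates the tally contract (range, key, or manifest lookup)."""


class ManifestError(ValueError):
    """A run manifest is internally inconsistent."""


def field_sample_id(site_id: str, event_index: int, replicate: int) -> str:
    """Canonical sample identifier for one replicate water sample."""
    return f"{site_id}.e{event_index:02d}.r{replicate}"


class Site(BaseModel):
    site_id: str
    water_body_type: Literal["river", "lake", "reservoir"]

    @field_validator("site_id")
    @classmethod
    def _id_ok(cls, v: str) -> str:
        if not _ID_RE.match(v):
            raise ValueError(
                f"site_id {v!r} must match [A-Za-z0-9_-]+ (no dots/whitespace)"
            )
        return v


class SamplingEvent(BaseModel):
    event_index: int = Field(ge=1)
    label: str = ""


class ControlSample(BaseModel):
    sample_id: str
    kind: Literal["positive", "negative"]
    expected_taxa: list[str] = Field(default_factory=list)
    plate: int = 1

    @model_validator(mode="after")
    def _expected_only_positive(self) -> "ControlSample":
        if self.kind == "negative" and self.expected_taxa:
            raise ValueError(f"negative control {self.sample_id} lists expected_taxa")
        return self


class RunManifest(BaseModel):
    """Design of one sequencing run: sites, events, replicates, controls."""

    run_id: str = "run"
    sites: list[Site]
    events: list[SamplingEvent]
    replicates_per_event: int = Field(default=6, ge=1)
    controls: list[ControlSample] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "RunManifest":
        self.events = sorted(self.events, key=lambda e: e.event_index)
        idx = [e.event_index for e in self.events]
        if len(set(idx)) != len(idx):
            raise ValueError("event indices must be strictly increasing (duplicates found)")
        site_ids = [s.site_id for s in self.sites]
        if len(set(site_ids)) != len(site_ids):
            dup = sorted({s for s in site_ids if site_ids.count(s) > 1})
            raise ValueError(f"duplicate site_id(s): {dup}")
        ctl_ids = [c.sample_id for c in self.controls]
        if len(set(ctl_ids)) != len(ctl_ids):
            raise ValueError("duplicate control sample_id")
        overlap = set(ctl_ids) & set(self.field_sample_ids())
        if overlap:
            raise ValueError(f"control sample_id collides with field sample id: {sorted(overlap)}")
        return self

    # -- lookup helpers -------------------------------------------------

    def event_indices(self) -> list[int]:
        return [e.event_index for e in self.events]

    def field_sample_ids(self) -> list[str]:
        return [
            field_sample_id(s.site_id, e.event_index, r)
            for s in self.sites
            for e in self.events
            for r in range(1, self.replicates_per_event + 1)
        ]

    def all_sample_ids(self) -> list[str]:
        return self.field_sample_ids() + [c.sample_id for c in self.controls]

    def control_ids(self, kind: str | None = None) -> list[str]:
        return [c.sample_id for c in self.controls if kind is None or c.kind == kind]

    def water_body_of(self, site_id: str) -> str:
        for s in self.sites:
            if s.site_id == site_id:
                return s.water_body_type
        raise KeyError(site_id)

    @staticmethod
    def parse_sample_id(sample_id: str) -> tuple[str, int, int] | None:
        """Split a field sample id into (site_id, event_index, replicate); None for controls."""
        m = _SAMPLE_RE.match(sample_id)
        if m is None:
            return None
        return m.group("site"), int(m.group("event")), int(m.group("rep"))


def read_manifest(path: str | Path) -> RunManifest:
    """Load and validate a run manifest from JSON; events are sorted on load."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        return RunManifest.model_validate_json(text)
    except Exception as exc:  # pydantic ValidationError is a ValueError subclass? keep explicit
        raise ManifestError(f"invalid manifest {path}: {exc}") from exc


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    Path(path).write_text(manifest.model_dump_json(indent=2) + "\n", encoding="utf-8")


def _coerce_int(df: pd.DataFrame, col: str) -> None:
    try:
        df[col] = df[col].astype("int64")
    except (ValueError, TypeError) as exc:
        raise TallyValidationError(f"column {col!r} is not integer-valued: {exc}") from exc


def validate_tallies(df: pd.DataFrame, manifest: RunManifest) -> pd.DataFrame:
    """Validate a raw tally frame against the manifest and aggregate duplicates.

    Duplicate (sample_id, primer_id, taxon) rows are summed; every sample id
    must resolve to a manifest field sample or a declared control. Returns a
    canonically sorted frame with exactly one row per key.
    """
    missing = [c for c in TALLY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"tally table missing column(s): {', '.join(missing)}")
    df = df[TALLY_COLUMNS].copy()
    for col in ("event_index", "replicate", "reads"):
        _coerce_int(df, col)

    neg = df.index[df["reads"] < 0]
    if len(neg):
        # +2: one for the header line, one for 0- vs 1-based indexing
        raise TallyValidationError(f"negative reads at data row {int(neg[0]) + 2}")
    bad_rank = sorted(set(df["rank"]) - set(RANKS))
    if bad_rank:
        raise TallyValidationError(f"unknown rank(s): {bad_rank}")

    known = set(manifest.all_sample_ids())
    unknown = sorted(set(df["sample_id"]) - known)
    if unknown:
        raise TallyValidationError(f"unknown sample_id(s): {unknown[:5]}")

    ctl = set(manifest.control_ids())
    for sid, sub in df.groupby("sample_id", sort=False):
        if sid in ctl:
            continue
        site, event, rep = RunManifest.parse_sample_id(sid)  # type: ignore[misc]
        ok = (
            (sub["site_id"] == site).all()
            and (sub["event_index"] == event).all()
            and (sub["replicate"] == rep).all()
        )
        if not ok:
            raise TallyValidationError(
                f"sample {sid}: site/event/replicate columns disagree with sample_id"
            )

    key = ["sample_id", "primer_id", "taxon"]
    carried = ["site_id", "event_index", "replicate", "rank"]
    ncomb = df.drop_duplicates(subset=key + carried)[key].value_counts()
    if (ncomb > 1).any():
        bad = ncomb[ncomb > 1].index[0]
        raise TallyValidationError(f"conflicting rank/site metadata for key {tuple(bad)}")
    out = (
        df.groupby(key + carried, as_index=False, sort=False)["reads"]
        .sum()
        .loc[:, TALLY_COLUMNS]
    )
    return sort_table(out)


def sort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Canonical, deterministic row order shared by all writers."""
    return df.sort_values(TABLE_SORT, kind="mergesort").reset_index(drop=True)


def read_tally_table(path: str | Path, manifest: RunManifest) -> pd.DataFrame:
    """Read a tally TSV, validate it against the manifest, and aggregate duplicates."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site_id": str,
                                                "primer_id": str, "taxon": str, "rank": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty tally table: {path}") from exc
    return validate_tallies(df, manifest)


def write_tally_table(df: pd.DataFrame, path: str | Path) -> None:
    if df.empty:
        raise ValueError("refusing to write an empty tally table")
    missing = [c for c in TALLY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"tally table missing column(s): {', '.join(missing)}")
    sort_table(df[TALLY_COLUMNS]).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_detection_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a detection CSV; byte-stable for a fixed table (canonical sort)."""
    if df.empty:
        raise ValueError("refusing to write an empty detection table")
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"detection table missing column(s): {', '.join(missing)}")
    bad = sorted(set(df["category"]) - set(CATEGORIES))
    if bad:
        raise TallyValidationError(f"unknown detection categories: {bad}")
    sort_table(df[DETECTION_COLUMNS]).to_csv(path, index=False, lineterminator="\n")


def read_detection_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "site_id": str, "primer_id": str,
                                  "taxon": str, "rank": str, "category": str,
                                  "threshold_run_id": str})
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"detection table missing column(s): {', '.join(missing)}")
    for col in ("event_index", "replicate", "reads"):
        _coerce_int(df, col)
    return sort_table(df)


def tallies_from_records(records: Iterable[dict]) -> pd.DataFrame:
    """Build a canonical tally frame from an iterable of dict records."""
    df = pd.DataFrame.from_records(list(records), columns=TALLY_COLUMNS)
    for col in ("event_index", "replicate", "reads"):
        df[col] = df[col].astype("int64")
    return sort_table(df)
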