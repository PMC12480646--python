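"""Monitoring/management decision framework for invasive-species eDNA screens.

Detection categories map to graded responses: a non-detection keeps the taxon
in the routine multi-species screening rotation; a low detection calls for
eDNA re-sampling and a traditional survey before anything escalates; a
positive (or survey-confirmed) detection triggers the full escalation set —
expanded screening sites, traditional surveys to localize the invasion,
agency notification, tracking-database entry, and containment/eradication
planning. Detection histories escalate: repeated low detections across events
or a visual/survey confirmation promote a taxon to confirmed; a dedicated
negative follow-up campaign (repeat eDNA plus targeted traditional surveys,
all negative) demotes a lone low detection back to "not observed".

Plate-control QC lives here too: negative controls flag contamination when
any of their tallies classify above non-detection, and positive controls
report which expected mock-community taxa their primers failed to recover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

#: Effective categories ordered by strength of evidence.
CATEGORY_ORDER = {"not_detected": 0, "low": 1, "positive": 2, "confirmed": 2}

ACTIONS = {
    "not_detected": frozenset({"continue_screening"}),
    "low": frozenset({"resample_edna", "traditional_survey"}),
    "positive": frozenset(
        {
            "expand_screening_sites",
            "traditional_survey",
            "notify_agencies",
            "add_to_tracking",
            "containment_and_eradication_planning",
        }
    ),
}
ACTIONS["confirmed"] = ACTIONS["positive"]


@dataclass(frozen=True)
class HistoryEntry:
    event: int
    category: str
    confirmed_by_survey: bool = False


@dataclass
class DetectionHistory:
    """Ordered detection record for one (site, taxon) pair."""

    site_id: str
    taxon: str
    entries: list[HistoryEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        events = [e.event for e in self.entries]
        if any(b <= a for a, b in zip(events, events[1:])):
            raise ValueError(
                f"history for ({self.site_id}, {self.taxon}): events must strictly increase"
            )

    def add(self, event: int, category: str, confirmed_by_survey: bool = False) -> None:
        if self.entries and event <= self.entries[-1].event:
            raise ValueError("events must strictly increase")
        self.entries.append(HistoryEntry(event, category, confirmed_by_survey))


def escalate(
    history: DetectionHistory,
    repeat_low_threshold: int = 2,
    followup_negative: bool = False,
) -> str:
    """Effective category of a detection history.

    Any positive detection, or a survey confirmation, or at least
    ``repeat_low_threshold`` low detections across distinct events, confirms
    the taxon. A single unconfirmed low detection stays low — unless a
    dedicated follow-up campaign came back negative, in which case the taxon
    is catalogued as not observed and returns to routine screening.
    """
    if not history.entries:
        raise ValueError("empty detection history")
    if any(e.category in ("positive", "confirmed") for e in history.entries):
        return "confirmed"
    if any(e.confirmed_by_survey for e in history.entries):
        return "confirmed"
    n_low = sum(1 for e in history.entries if e.category == "low")
    if n_low >= repeat_low_threshold:
        return "confirmed"
    if n_low >= 1:
        return "not_detected" if followup_negative else "low"
    return "not_detected"


def recommend_action(category: str, history: DetectionHistory | None = None) -> frozenset[str]:
    """Actions for a detection category, upgraded by history escalation.

    With no (or empty) history the category speaks for itself; otherwise the
    stronger of the category and the escalated history governs.
    """
    if category not in CATEGORY_ORDER:
        raise ValueError(f"unknown category {category!r}")
    effective = category
    if history is not None and history.entries:
        esc = escalate(history)
        if CATEGORY_ORDER[esc] > CATEGORY_ORDER[effective]:
            effective = esc
    return ACTIONS[effective]


@dataclass(frozen=True)
class ContaminationFlag:
    """A negative-control tally that classified above non-detection."""

    sample_id: str
    plate: int
    primer_id: str
    taxon: str
    category: str
    reads: int


def check_negative_controls(detections: pd.DataFrame, manifest) -> list[ContaminationFlag]:
    """Flag every negative-control tally with a low or positive category."""
    negatives = {c.sample_id: c.plate for c in manifest.controls if c.kind == "negative"}
    if not negatives:
        warnings.warn("manifest declares no negative controls; contamination QC skipped")
        return []
    sub = detections[
        detections["sample_id"].isin(negatives) & (detections["category"] != "not_detected")
    ]
    return [
        ContaminationFlag(
            sample_id=row.sample_id,
            plate=negatives[row.sample_id],
            primer_id=row.primer_id,
            taxon=row.taxon,
            category=row.category,
            reads=int(row.reads),
        )
        for row in sub.itertuples(index=False)
    ]


@dataclass(frozen=True)
class PositiveControlReport:
    """Recovery of the expected mock-community taxa in one positive control."""

    sample_id: str
    plate: int
    expected: tuple[str, ...]
    detected: tuple[str, ...]
    missing: tuple[str, ...]


def verify_positive_controls(detections: pd.DataFrame, manifest) -> list[PositiveControlReport]:
    """Per positive control, which expected taxa were recovered vs missing.

    A taxon counts as detected if any of its tallies in the control sample is
    low or positive; missing taxa indicate likely primer failure for that
    target on this run.
    """
    reports = []
    for ctl in manifest.controls:
        if ctl.kind != "positive":
            continue
        if not ctl.expected_taxa:
            raise ValueError(f"positive control {ctl.sample_id} has empty expected_taxa")
        sub = detections[
            (detections["sample_id"] == ctl.sample_id)
            & (detections["category"] != "not_detected")
        ]
        detected = sorted(set(sub["taxon"]) & set(ctl.expected_taxa))
        missing = sorted(set(ctl.expected_taxa) - set(detected))
        reports.append(
            PositiveControlReport(
                sample_id=ctl.sample_id,
                plate=ctl.plate,
                expected=tuple(sorted(ctl.expected_taxa)),
                detected=tuple(detected),
                missing=tuple(missing),
            )
        )
    return reports


def histories_from_detections(detections: pd.DataFrame) -> dict[tuple[str, str], DetectionHistory]:
    """Build per-(site, taxon) histories from a field detection table.

    The per-event category is the best attained over replicates and primers
    (positive > low > not_detected). Control rows (event_index 0) are ignored.
    """
    field_rows = detections[detections["event_index"] >= 1]
    histories: dict[tuple[str, str], DetectionHistory] = {}
    grouped = field_rows.groupby(["site_id", "taxon", "event_index"])["category"].agg(
        lambda s: max(s, key=lambda c: CATEGORY_ORDER[c])
    )
    for (site, taxon, event), cat in grouped.sort_index().items():
        hist = histories.setdefault((site, taxon), DetectionHistory(site_id=site, taxon=taxon))
        hist.add(int(event), cat)
    return histories
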