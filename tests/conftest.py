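import pandas as pd
import pytest

from ednadetect.io import (
    ControlSample,
    RunManifest,
    SamplingEvent,
    Site,
    field_sample_id,
    tallies_from_records,
)


@pytest.fixture
def small_manifest() -> RunManifest:
    """One river, two events, three replicates, one control pair."""
    return RunManifest(
        run_id="test-run",
        sites=[Site(site_id="river1", water_body_type="river")],
        events=[SamplingEvent(event_index=1), SamplingEvent(event_index=2)],
        replicates_per_event=3,
        controls=[
            ControlSample(sample_id="plate01-pos", kind="positive",
                          expected_taxa=["taxonA", "taxonB"]),
            ControlSample(sample_id="plate01-neg", kind="negative"),
        ],
    )


@pytest.fixture
def toy_manifest() -> RunManifest:
    """Degenerate single-sample design for the worked 7-tally example."""
    return RunManifest(
        run_id="toy",
        sites=[Site(site_id="siteA", water_body_type="lake")],
        events=[SamplingEvent(event_index=1)],
        replicates_per_event=1,
    )


#: The worked tail example: total 10 000 reads, budgets 60 / 100 reads,
#: hand cumulative sums give cutoffs (14, 80) and categories 4/1/2.
TOY_READS = [1, 2, 3, 14, 80, 300, 9600]


@pytest.fixture
def toy_tallies(toy_manifest) -> pd.DataFrame:
    sid = field_sample_id("siteA", 1, 1)
    return tallies_from_records(
        dict(
            sample_id=sid,
            site_id="siteA",
            event_index=1,
            replicate=1,
            primer_id="primer01",
            taxon=f"taxon{i:02d}",
            rank="species",
            reads=r,
        )
        for i, r in enumerate(TOY_READS, start=1)
    )


def make_detections(rows, run_id="test-run") -> pd.DataFrame:
    """Detection frame builder for summary/framework tests.

    ``rows``: iterables of (site, event, replicate, primer, taxon, category[, reads]).
    """
    records = []
    for row in rows:
        site, event, rep, primer, taxon, category = row[:6]
        reads = row[6] if len(row) > 6 else {"not_detected": 1, "low": 50, "positive": 5000}[category]
        records.append(
            dict(
                sample_id=field_sample_id(site, event, rep),
                site_id=site,
                event_index=event,
                replicate=rep,
                primer_id=primer,
                taxon=taxon,
                rank="species",
                reads=reads,
                category=category,
                threshold_run_id=run_id,
            )
        )
    return pd.DataFrame.from_records(records)
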