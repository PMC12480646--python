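"""Tally/manifest/detection table I/O: validation, aggregation, round trips."""

import json

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ednadetect.io import (
    ManifestError,
    RunManifest,
    SchemaError,
    TallyValidationError,
    field_sample_id,
    read_detection_table,
    read_manifest,
    read_tally_table,
    tallies_from_records,
    write_detection_table,
    write_manifest,
    write_tally_table,
)

HEADER = "sample_id\tsite_id\tevent_index\treplicate\tprimer_id\ttaxon\trank\treads"


def tsv(rows):
    return HEADER + "\n" + "\n".join("\t".join(map(str, r)) for r in rows) + "\n"


def field_row(manifest, taxon="taxonA", reads=10, event=1, rep=1, primer="p1"):
    site = manifest.sites[0].site_id
    return (field_sample_id(site, event, rep), site, event, rep, primer, taxon, "species", reads)


class TestReadTallyTable:
    def test_identity_round_trip(self, small_manifest, tmp_path):
        rows = [field_row(small_manifest, taxon=t) for t in ("a", "b", "c")]
        path = tmp_path / "t.tsv"
        path.write_text(tsv(rows))
        df = read_tally_table(path, small_manifest)
        assert len(df) == 3
        assert df["reads"].tolist() == [10, 10, 10]

    def test_duplicate_keys_summed(self, small_manifest, tmp_path):
        rows = [field_row(small_manifest, reads=5), field_row(small_manifest, reads=7)]
        path = tmp_path / "t.tsv"
        path.write_text(tsv(rows))
        df = read_tally_table(path, small_manifest)
        assert len(df) == 1
        assert df["reads"].iloc[0] == 12

    def test_negative_reads_cites_row(self, small_manifest, tmp_path):
        rows = [field_row(small_manifest), field_row(small_manifest, taxon="b", reads=-1)]
        path = tmp_path / "t.tsv"
        path.write_text(tsv(rows))
        with pytest.raises(TallyValidationError, match="row 3"):
            read_tally_table(path, small_manifest)

    def test_missing_column_named(self, small_manifest, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample_id\tsite_id\n x\ty\n")
        with pytest.raises(SchemaError, match="event_index"):
            read_tally_table(path, small_manifest)

    def test_unknown_sample_rejected(self, small_manifest, tmp_path):
        rows = [("ghost.e01.r1", "ghost", 1, 1, "p1", "a", "species", 5)]
        path = tmp_path / "t.tsv"
        path.write_text(tsv(rows))
        with pytest.raises(TallyValidationError, match="unknown sample_id"):
            read_tally_table(path, small_manifest)

    def test_control_rows_accepted(self, small_manifest, tmp_path):
        rows = [("plate01-neg", "-", 0, 0, "p1", "a", "species", 2)]
        path = tmp_path / "t.tsv"
        path.write_text(tsv(rows))
        df = read_tally_table(path, small_manifest)
        assert df["sample_id"].tolist() == ["plate01-neg"]

    @given(
        reads=st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=2),  # event
                st.integers(min_value=1, max_value=3),  # replicate
                st.sampled_from(["p1", "p2"]),
                st.sampled_from(["a", "b", "c"]),
                st.integers(min_value=0, max_value=1000),
            ),
            min_size=1,
            max_size=40,
        ),
        order_seed=st.integers(min_value=0, max_value=100),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_aggregation_order_independent(self, reads, order_seed):
        import tempfile
        from pathlib import Path

        manifest = RunManifest.model_validate(
            {
                "sites": [{"site_id": "river1", "water_body_type": "river"}],
                "events": [{"event_index": 1}, {"event_index": 2}],
                "replicates_per_event": 3,
            }
        )
        rows = [
            (field_sample_id("river1", e, r), "river1", e, r, p, t, "species", n)
            for e, r, p, t, n in reads
        ]
        shuffled = (
            pd.DataFrame(rows).sample(frac=1.0, random_state=order_seed).values.tolist()
        )
        with tempfile.TemporaryDirectory() as tmp:
            p1, p2 = Path(tmp) / "a.tsv", Path(tmp) / "b.tsv"
            p1.write_text(tsv(rows))
            p2.write_text(tsv(shuffled))
            pd.testing.assert_frame_equal(
                read_tally_table(p1, manifest), read_tally_table(p2, manifest)
            )


class TestDetectionTable:
    def _table(self, small_manifest):
        rows = [field_row(small_manifest, taxon=t, reads=n) for t, n in [("a", 5), ("b", 500)]]
        df = tallies_from_records(
            dict(zip(HEADER.split("\t"), r)) for r in rows
        )
        df["category"] = ["not_detected", "positive"]
        df["threshold_run_id"] = "test-run"
        return df

    def test_round_trip(self, small_manifest, tmp_path):
        df = self._table(small_manifest)
        path = tmp_path / "d.csv"
        write_detection_table(df, path)
        back = read_detection_table(path)
        pd.testing.assert_frame_equal(back, df)

    def test_two_writes_identical_bytes(self, small_manifest, tmp_path):
        df = self._table(small_manifest)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_detection_table(df, p1)
        write_detection_table(df.sample(frac=1.0, random_state=3), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_rejected(self, small_manifest, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            write_detection_table(self._table(small_manifest).iloc[0:0], tmp_path / "d.csv")

    def test_tally_round_trip(self, small_manifest, tmp_path):
        rows = [field_row(small_manifest, taxon=t) for t in ("a", "b")]
        df = tallies_from_records(dict(zip(HEADER.split("\t"), r)) for r in rows)
        path = tmp_path / "t.tsv"
        write_tally_table(df, path)
        pd.testing.assert_frame_equal(read_tally_table(path, small_manifest), df)


class TestManifest:
    def _doc(self):
        return {
            "run_id": "fig1",
            "sites": [
                {"site_id": "river1", "water_body_type": "river"},
                {"site_id": "river2", "water_body_type": "river"},
                {"site_id": "river3", "water_body_type": "river"},
                {"site_id": "lake1", "water_body_type": "lake"},
                {"site_id": "lake2", "water_body_type": "lake"},
                {"site_id": "reservoir1", "water_body_type": "reservoir"},
            ],
            "events": [{"event_index": i} for i in range(1, 11)],
            "replicates_per_event": 6,
        }

    def test_campaign_design_parses(self, tmp_path):
        """Three rivers, two lakes, one reservoir, ten biweekly events, six replicates."""
        path = tmp_path / "m.json"
        path.write_text(json.dumps(self._doc()))
        m = read_manifest(path)
        assert len(m.sites) == 6
        assert m.event_indices() == list(range(1, 11))
        assert len(m.field_sample_ids()) == 6 * 10 * 6

    def test_events_sorted_on_load(self, tmp_path):
        doc = self._doc()
        doc["events"] = doc["events"][::-1]
        path = tmp_path / "m.json"
        path.write_text(json.dumps(doc))
        assert read_manifest(path).event_indices() == list(range(1, 11))

    def test_duplicate_site_rejected(self, tmp_path):
        doc = self._doc()
        doc["sites"].append({"site_id": "river1", "water_body_type": "lake"})
        path = tmp_path / "m.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ManifestError, match="duplicate site_id"):
            read_manifest(path)

    def test_control_colliding_with_field_id_rejected(self, tmp_path):
        doc = self._doc()
        doc["controls"] = [{"sample_id": "river1.e01.r1", "kind": "negative"}]
        path = tmp_path / "m.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ManifestError, match="collides"):
            read_manifest(path)

    def test_manifest_round_trip(self, small_manifest, tmp_path):
        path = tmp_path / "m.json"
        write_manifest(small_manifest, path)
        assert read_manifest(path) == small_manifest
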