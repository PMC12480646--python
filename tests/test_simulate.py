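"""Simulator ground truth: conservation, swap statistics, controls, seasonality."""

import math

import numpy as np
import pandas as pd
import pytest

from ednadetect.simulate import (
    ParameterError,
    SimParams,
    TaxonSpec,
    TrueState,
    add_controls,
    make_manifest,
    random_panel,
    seasonal_scenario,
    simulate_run,
    study_design,
)


def small_design(seed=0, swap_rate=0.006, **kw):
    manifest = make_manifest(n_rivers=1, n_lakes=1, n_reservoirs=0, n_events=2,
                             replicates=3, run_id="sim-test")
    taxa = random_panel(manifest, n_taxa=8, n_primers=4, seed=seed)
    params = SimParams(taxa=taxa, swap_rate=swap_rate, seed=seed, **kw)
    return manifest, params


class TestSimulateRun:
    def test_no_swap_stays_inside_occupancy(self):
        manifest, params = small_design(swap_rate=0.0)
        truth, tallies = simulate_run(manifest, params)
        for row in tallies.itertuples(index=False):
            assert (row.site_id, row.taxon, row.primer_id) in truth.occupancy
        assert truth.ledger == []

    def test_read_conservation(self):
        for seed in (0, 1, 2):
            manifest, params = small_design(seed=seed, swap_rate=0.03)
            truth, tallies = simulate_run(manifest, params)
            assert tallies["reads"].sum() == sum(truth.pre_swap.values())

    def test_swapped_read_count_binomial(self):
        """Observed hops within 4 binomial SD of r*N over a seeded run."""
        manifest, params = study_design(seed=11, swap_rate=0.006)
        truth, _ = simulate_run(manifest, params)
        n = sum(truth.pre_swap.values())
        mean = 0.006 * n
        sd = math.sqrt(n * 0.006 * 0.994)
        assert abs(truth.n_swapped_reads() - mean) <= 4 * sd

    def test_same_seed_byte_identical(self, tmp_path):
        from ednadetect.io import write_tally_table

        paths = []
        for name in ("a.tsv", "b.tsv"):
            manifest, params = small_design(seed=5, swap_rate=0.01)
            _, tallies = simulate_run(manifest, params)
            path = tmp_path / name
            write_tally_table(tallies, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_swap_rate_out_of_range(self):
        manifest, params = small_design()
        with pytest.raises((ParameterError, ValueError)):
            SimParams(taxa=params.taxa, swap_rate=0.07)

    def test_swap_tail_mass_tracks_rate(self):
        """Reads in swap-only combos ≈ the share of hops landing outside occupancy."""
        manifest, params = study_design(seed=3, swap_rate=0.006)
        truth, tallies = simulate_run(manifest, params)
        from ednadetect.io import RunManifest

        swap_only = 0
        for row in tallies.itertuples(index=False):
            if (row.site_id, row.taxon, row.primer_id) not in truth.occupancy:
                swap_only += row.reads
        total = tallies["reads"].sum()
        # swap-only mass is bounded by the total hopped mass and is its
        # dominant share when occupancy covers about half the run
        assert swap_only <= truth.n_swapped_reads()
        assert swap_only / total < 0.006
        assert swap_only / total > 0.0005

    def test_swap_tallies_dominated_by_true_tallies(self):
        manifest, params = study_design(seed=7)
        truth, tallies = simulate_run(manifest, params)
        swap_vals, true_vals = [], []
        for row in tallies.itertuples(index=False):
            if (row.site_id, row.taxon, row.primer_id) in truth.occupancy:
                true_vals.append(row.reads)
            else:
                swap_vals.append(row.reads)
        assert np.median(swap_vals) < np.median(true_vals)

    def test_truth_json_round_trip(self, tmp_path):
        manifest, params = small_design(seed=4, swap_rate=0.02)
        truth, _ = simulate_run(manifest, params)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = TrueState.from_json(path)
        assert back.occupancy == truth.occupancy
        assert back.pre_swap == truth.pre_swap
        assert back.ledger == truth.ledger


class TestAddControls:
    def test_positive_control_panel_coverage(self):
        """Certain control detection yields one nonzero tally per expected taxon × primer."""
        manifest, params = small_design(swap_rate=0.0, control_detection_prob=1.0)
        for ctl in manifest.controls:
            if ctl.kind == "positive":
                ctl.expected_taxa = [t.name for t in params.taxa]
        truth, tallies = simulate_run(manifest, params)
        tallies, truth = add_controls(tallies, manifest, params, truth)
        pos_ids = manifest.control_ids("positive")
        expected = sum(
            len(t.primers) * len(pos_ids) for t in params.taxa
        )
        got = tallies[tallies["sample_id"].isin(pos_ids)]
        assert len(got) == expected
        assert (got["reads"] >= 1).all()

    def test_negative_control_empty_without_swaps(self):
        manifest, params = small_design(swap_rate=0.0)
        for ctl in manifest.controls:
            if ctl.kind == "positive":
                ctl.expected_taxa = [params.taxa[0].name]
        truth, tallies = simulate_run(manifest, params)
        tallies, truth = add_controls(tallies, manifest, params, truth)
        neg = tallies[tallies["sample_id"].isin(manifest.control_ids("negative"))]
        assert neg.empty

    def test_negative_control_reads_trace_to_ledger(self):
        manifest, params = study_design(seed=9, swap_rate=0.06)
        truth, tallies = simulate_run(manifest, params)
        tallies, truth = add_controls(tallies, manifest, params, truth)
        for neg in manifest.control_ids("negative"):
            rows = tallies[tallies["sample_id"] == neg]
            ledger_in = {}
            for ev in truth.swapped_into(neg):
                key = (ev.primer_id, ev.taxon)
                ledger_in[key] = ledger_in.get(key, 0) + ev.n_reads
            table_in = {
                (r.primer_id, r.taxon): r.reads for r in rows.itertuples(index=False)
            }
            assert table_in == {k: v for k, v in ledger_in.items() if v > 0}

    def test_empty_expected_taxa_rejected(self):
        manifest, params = small_design()
        truth, tallies = simulate_run(manifest, params)
        with pytest.raises(ValueError, match="empty expected_taxa"):
            add_controls(tallies, manifest, params, truth)


class TestSeasonalScenario:
    def test_negative_multiplier_rejected(self):
        manifest, params = small_design()
        with pytest.raises(ParameterError, match="negative"):
            seasonal_scenario(manifest, params, {"river": [1.0, -0.5]})

    def test_wrong_length_rejected(self):
        manifest, params = small_design()
        with pytest.raises(ParameterError, match="entries"):
            seasonal_scenario(manifest, params, {"river": [1.0]})

    def test_all_zero_curve_silences_water_body(self):
        manifest, params = small_design(swap_rate=0.0)
        schedule = seasonal_scenario(manifest, params, {"river": [0.0, 0.0]})
        truth, tallies = simulate_run(manifest, params, schedule)
        river_rows = tallies[tallies["site_id"] == "river1"]
        assert river_rows.empty

    def test_flat_curve_matches_unscheduled_run(self):
        manifest, params = small_design(seed=2, swap_rate=0.01)
        schedule = seasonal_scenario(manifest, params, {"river": [1.0, 1.0]})
        t1, d1 = simulate_run(manifest, params)
        t2, d2 = simulate_run(manifest, params, schedule)
        pd.testing.assert_frame_equal(d1, d2)

    def test_early_river_peak_saturates_first(self):
        """A river availability curve peaking at event 1 saturates its cumulative
        detection curve earlier than a late-peaking lake curve (seeded run)."""
        from ednadetect.summaries import cumulative_curves
        from ednadetect.thresholds import classify_run

        manifest = make_manifest(n_rivers=1, n_lakes=1, n_reservoirs=0, n_events=6,
                                 replicates=6, run_id="season")
        taxa = random_panel(manifest, n_taxa=12, n_primers=6, seed=21, occupancy_prob=1.0)
        params = SimParams(taxa=taxa, detection_prob=0.35, seed=21)
        schedule = seasonal_scenario(
            manifest,
            params,
            {
                "river": [2.5, 1.0, 0.3, 0.1, 0.1, 0.1],
                "lake": [0.1, 0.1, 0.1, 0.3, 1.0, 2.5],
            },
        )
        truth, tallies = simulate_run(manifest, params, schedule)
        _, det = classify_run(tallies, manifest)
        curves = cumulative_curves(det, manifest)

        def saturation_event(group):
            sub = curves[curves["group"] == group]
            final = sub["cumulative_taxa"].iloc[-1]
            return int(sub.loc[sub["cumulative_taxa"] == final, "event_index"].iloc[0])

        assert saturation_event("river") < saturation_event("lake")
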