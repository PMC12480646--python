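"""Derive the run's tail cutoffs and call every tally not_detected/low/positive.

Reads results/run/ from the simulation step, computes the 0.6%/1.0%
cumulative-read cutoffs from the field tallies (controls excluded from the
distribution), classifies everything, and reports control QC.
"""

import json
from pathlib import Path

from ednadetect.framework import check_negative_controls, verify_positive_controls
from ednadetect.io import read_manifest, read_tally_table, write_detection_table
from ednadetect.thresholds import classify_run

RUN = Path("results/run")


def main() -> None:
    manifest = read_manifest(RUN / "manifest.json")
    tallies = read_tally_table(RUN / "tallies.tsv", manifest)
    thresholds, detections = classify_run(tallies, manifest)
    write_detection_table(detections, RUN / "detections.csv")
    (RUN / "thresholds.json").write_text(
        json.dumps(thresholds.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    counts = detections["category"].value_counts().to_dict()
    print(
        f"total classified reads {thresholds.total_reads}; "
        f"cutoffs: drop <= {thresholds.cutoff_drop}, low <= {thresholds.cutoff_low}"
    )
    print(f"categories: {counts}")
    flags = check_negative_controls(detections, manifest)
    print(f"negative-control contamination flags: {len(flags)}")
    for report in verify_positive_controls(detections, manifest):
        print(
            f"positive control {report.sample_id}: {len(report.detected)}/"
            f"{len(report.expected)} expected taxa recovered, missing {list(report.missing)}"
        )


if __name__ == "__main__":
    main()
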