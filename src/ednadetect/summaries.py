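"""Reporting surfaces for a season of detections.

Three summaries mirror how a monitoring campaign reads its results:

* **Replicate profiles** — for each (site, event, taxon), in how many of the
  R replicate water samples (default six 500-mL grabs per site visit) the
  taxon was a positive detection; a replicate counts once even if several
  primers fired, and low detections do not count.
* **Site × species matrix** — one cell per (site, taxon): the best category
  attained over the whole season (positive > low > not_detected).
* **Cumulative detection curves** — per water-body type, the running number
  of distinct taxa with at least one positive detection up to each biweekly
  event, plus the per-event positive-species counts used to find the peak
  sampling window (rivers tend to saturate early, lakes late, reservoirs in
  between).
"""

from __future__ import annotations

import pandas as pd

from .io import RunManifest

_CAT_ORDER = {"not_detected": 0, "low": 1, "positive": 2}


def _field_rows(detections: pd.DataFrame, manifest: RunManifest) -> pd.DataFrame:
    ctl = set(manifest.control_ids())
    return detections[~detections["sample_id"].isin(ctl)]


def replicate_profile(detections: pd.DataFrame, manifest: RunManifest) -> pd.DataFrame:
    """Positive-detection replicate counts per (site, event, taxon).

    Output columns: site_id, event_index, taxon, k (replicates with >= 1
    positive tally on any primer), n_replicates. One row per (site, event,
    taxon) present in the detection table, whatever its categories.
    """
    rows = _field_rows(detections, manifest)
    if (rows["replicate"] > manifest.replicates_per_event).any():
        bad = rows.loc[rows["replicate"] > manifest.replicates_per_event, "replicate"].iloc[0]
        raise ValueError(
            f"replicate index {bad} exceeds manifest replicates_per_event "
            f"({manifest.replicates_per_event})"
        )
    pos = rows[rows["category"] == "positive"]
    k = (
        pos.groupby(["site_id", "event_index", "taxon"])["replicate"]
        .nunique()
        .rename("k")
    )
    domain = rows[["site_id", "event_index", "taxon"]].drop_duplicates()
    out = domain.merge(k, how="left", on=["site_id", "event_index", "taxon"])
    out["k"] = out["k"].fillna(0).astype("int64")
    out["n_replicates"] = manifest.replicates_per_event
    return out.sort_values(["site_id", "event_index", "taxon"], kind="mergesort").reset_index(
        drop=True
    )


def site_species_matrix(detections: pd.DataFrame, manifest: RunManifest) -> pd.DataFrame:
    """Season-wide site × taxon matrix of best attained categories.

    Rows are manifest sites, columns the taxa appearing in the detection
    table; a cell is the maximum category over all events, replicates and
    primers, or not_detected if the pair never appears.
    """
    rows = _field_rows(detections, manifest)
    taxa = sorted(rows["taxon"].unique())
    sites = [s.site_id for s in manifest.sites]
    best = (
        rows.assign(_ord=rows["category"].map(_CAT_ORDER))
        .groupby(["site_id", "taxon"])["_ord"]
        .max()
    )
    inv = {v: k for k, v in _CAT_ORDER.items()}
    mat = pd.DataFrame("not_detected", index=pd.Index(sites, name="site_id"),
                       columns=pd.Index(taxa, name="taxon"))
    for (site, taxon), o in best.items():
        if site in mat.index:
            mat.loc[site, taxon] = inv[int(o)]
    return mat


def cumulative_curves(
    detections: pd.DataFrame,
    manifest: RunManifest,
    per_site: bool = False,
) -> pd.DataFrame:
    """Cumulative distinct positive taxa and per-event positive counts.

    Grouped by water-body type (pooled across its sites) by default, or per
    site with ``per_site=True``. Output columns: group, event_index,
    positive_taxa (distinct taxa positive *at* that event), new_taxa (first
    positive detections at that event), cumulative_taxa (non-decreasing).
    Every manifest event appears, zero-filled where nothing was detected.
    """
    rows = _field_rows(detections, manifest)
    pos = rows[rows["category"] == "positive"].copy()
    if per_site:
        pos["group"] = pos["site_id"]
        groups = [s.site_id for s in manifest.sites]
    else:
        wbt = {s.site_id: s.water_body_type for s in manifest.sites}
        pos["group"] = pos["site_id"].map(wbt)
        groups = sorted({s.water_body_type for s in manifest.sites})
    events = manifest.event_indices()

    records = []
    for group in groups:
        sub = pos[pos["group"] == group]
        first_event = sub.groupby("taxon")["event_index"].min()
        seen = 0
        for ev in events:
            at_event = sub.loc[sub["event_index"] == ev, "taxon"].nunique()
            new = int((first_event == ev).sum())
            seen += new
            records.append(
                dict(group=group, event_index=ev, positive_taxa=int(at_event),
                     new_taxa=new, cumulative_taxa=seen)
            )
    return pd.DataFrame.from_records(
        records, columns=["group", "event_index", "positive_taxa", "new_taxa", "cumulative_taxa"]
    )


def peak_event(per_event_counts: pd.Series | dict[int, int]) -> int:
    """Event index with the highest positive-species count; ties go to the earliest."""
    if isinstance(per_event_counts, dict):
        per_event_counts = pd.Series(per_event_counts)
    if len(per_event_counts) == 0:
        raise ValueError("no events to search for a peak")
    s = per_event_counts.sort_index()
    return int(s.index[s.to_numpy().argmax()])


def peak_events_by_group(curves: pd.DataFrame) -> dict[str, int]:
    """Peak sampling event per group from a :func:`cumulative_curves` table."""
    return {
        group: peak_event(sub.set_index("event_index")["positive_taxa"])
        for group, sub in curves.groupby("group")
    }


def plot_cumulative_curves(curves: pd.DataFrame, path: str) -> None:
    """Line plot of cumulative distinct positive taxa per group (PNG/PDF by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for group, sub in curves.groupby("group"):
        ax.plot(sub["event_index"], sub["cumulative_taxa"], marker="o", label=str(group))
    ax.set_xlabel("sampling event")
    ax.set_ylabel("cumulative positive taxa")
    ax.legend(title="water body")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
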