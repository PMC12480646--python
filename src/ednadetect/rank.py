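"""Percent-identity rank assignment for consensus amplicon sequences.

A query sequence is matched to its best reference by global percent identity
and assigned the deepest taxonomic rank whose identity threshold it attains.
The default thresholds (species 97.8, genus 96.2, family 88.3, order 81.21,
class 80.91 — percent identity against the best reference) were tuned on
mock-community positive-control data; identity below the class threshold
leaves the sequence unclassified. Boundaries are inclusive: identity exactly
equal to a threshold attains that rank.

Identity is computed from a global alignment scored match=+1, mismatch=0,
with gap columns counted like mismatches (identity = matches / alignment
columns); among maximum-match alignments the one with fewest gap columns is
taken. This is a deliberately simple single-best-hit scheme — no k-mer
database search, consensus building, or lowest-common-ancestor logic — that
preserves the threshold semantics of the full classification pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import Align, SeqIO
from pydantic import BaseModel, Field, model_validator

#: Ranks ordered deepest → shallowest, as (rank, lineage position).
_RANK_ORDER = ("species", "genus", "family", "order", "class")
_LINEAGE_POS = {"class": 0, "order": 1, "family": 2, "genus": 3, "species": 4}

_IUPAC = set("ACGTUNRYSWKMBDHV")


class RankThresholds(BaseModel):
    """Minimum percent identity required to assign each rank (inclusive)."""

    species: float = Field(default=97.8, ge=0, le=100)
    genus: float = Field(default=96.2, ge=0, le=100)
    family: float = Field(default=88.3, ge=0, le=100)
    order: float = Field(default=81.21, ge=0, le=100)
    class_: float = Field(default=80.91, ge=0, le=100, alias="class")

    model_config = {"populate_by_name": True}

    @model_validator(mode="after")
    def _strictly_decreasing(self) -> "RankThresholds":
        vals = [self.species, self.genus, self.family, self.order, self.class_]
        if not all(a > b for a, b in zip(vals, vals[1:])):
            raise ValueError("thresholds must strictly decrease from species to class")
        return self

    def threshold_for(self, rank: str) -> float:
        return getattr(self, "class_" if rank == "class" else rank)


DEFAULT_RANK_THRESHOLDS = RankThresholds()


@dataclass(frozen=True)
class ReferenceRecord:
    """A reference sequence with its complete five-rank lineage."""

    ref_id: str
    sequence: str
    lineage: tuple[str, str, str, str, str]  # (class, order, family, genus, species)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"reference {self.ref_id}: empty sequence")
        if len(self.lineage) != 5 or not all(self.lineage):
            raise ValueError(f"reference {self.ref_id}: incomplete 5-rank lineage")


@dataclass(frozen=True)
class QueryRecord:
    """A consensus sequence annotated with its sample, primer, and read weight."""

    query_id: str
    sequence: str
    sample_id: str
    primer_id: str
    weight: int = 1


def _check_sequence(label: str, seq: str) -> str:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    seq = seq.upper()
    bad = sorted(set(seq) - _IUPAC)
    if bad:
        raise ValueError(f"{label}: non-IUPAC nucleotide character(s) {bad}")
    return seq


def percent_identity(query: str, reference: str) -> float:
    """Global percent identity between two nucleotide sequences, in [0, 100].

    identity = 100 × matched columns / alignment columns, for the global
    alignment maximizing matches (gap columns count as mismatched columns;
    ties resolved toward the fewest gap columns). Characters match only on
    exact equality, so ambiguity codes are not expanded.
    """
    q = _check_sequence("query", query)
    r = _check_sequence("reference", reference)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    # A sub-unit gap penalty never trades away a match; it only breaks ties
    # among maximum-match alignments toward the fewest gap columns.
    eps = 1.0 / (4.0 * (len(q) + len(r) + 1))
    aligner.open_gap_score = -eps
    aligner.extend_gap_score = -eps
    aln = aligner.align(q, r)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def assign_rank(identity: float, thresholds: RankThresholds | None = None) -> str:
    """Deepest rank whose threshold the identity attains; below class → unclassified."""
    thresholds = thresholds or DEFAULT_RANK_THRESHOLDS
    if not 0.0 <= identity <= 100.0:
        raise ValueError(f"identity {identity} outside [0, 100]")
    for rank in _RANK_ORDER:
        if identity >= thresholds.threshold_for(rank):
            return rank
    return "unclassified"


def best_reference(
    query: str, references: list[ReferenceRecord]
) -> tuple[ReferenceRecord, float]:
    """Single best-identity reference; ties broken by lexicographic ref_id."""
    if not references:
        raise ValueError("empty reference set")
    best_ref, best_ident = None, -1.0
    for ref in sorted(references, key=lambda x: x.ref_id):
        ident = percent_identity(query, ref.sequence)
        if ident > best_ident:
            best_ref, best_ident = ref, ident
    return best_ref, best_ident  # type: ignore[return-value]


def classify_sequences(
    queries: list[QueryRecord],
    references: list[ReferenceRecord],
    thresholds: RankThresholds | None = None,
) -> pd.DataFrame:
    """Classify queries and sum their read weights into tally rows.

    Each query is assigned its best reference's lineage truncated to the rank
    its identity supports; weights are summed per (sample, primer, taxon).
    Output columns: sample_id, primer_id, taxon, rank, reads. The total output
    reads always equal the total input weights.
    """
    if not references:
        raise ValueError("empty reference set")
    thresholds = thresholds or DEFAULT_RANK_THRESHOLDS
    rows = []
    for q in queries:
        ref, ident = best_reference(q.sequence, references)
        rank = assign_rank(ident, thresholds)
        if rank == "unclassified":
            taxon = "unclassified"
        else:
            taxon = ref.lineage[_LINEAGE_POS[rank]]
        rows.append(
            dict(sample_id=q.sample_id, primer_id=q.primer_id, taxon=taxon,
                 rank=rank, reads=int(q.weight))
        )
    df = pd.DataFrame(rows, columns=["sample_id", "primer_id", "taxon", "rank", "reads"])
    out = (
        df.groupby(["sample_id", "primer_id", "taxon", "rank"], as_index=False)["reads"]
        .sum()
        .sort_values(["sample_id", "primer_id", "taxon"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


# ---------------------------------------------------------------------------
# FASTA / lineage-table readers
# ---------------------------------------------------------------------------

def read_references(fasta_path: str | Path, lineage_path: str | Path) -> list[ReferenceRecord]:
    """Read reference sequences (FASTA) and their lineages (TSV).

    The lineage table has columns ``ref_id class order family genus species``;
    every FASTA record must have a lineage row.
    """
    lineages = pd.read_csv(lineage_path, sep="\t", dtype=str)
    need = ["ref_id", "class", "order", "family", "genus", "species"]
    missing = [c for c in need if c not in lineages.columns]
    if missing:
        raise ValueError(f"lineage table missing column(s): {missing}")
    lin = {
        row["ref_id"]: tuple(row[c] for c in need[1:])
        for _, row in lineages.iterrows()
    }
    refs = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in lin:
            raise ValueError(f"reference {rec.id} has no lineage row")
        refs.append(ReferenceRecord(ref_id=rec.id, sequence=str(rec.seq), lineage=lin[rec.id]))
    if not refs:
        raise ValueError("empty reference FASTA")
    return refs


def read_queries(fasta_path: str | Path) -> list[QueryRecord]:
    """Read annotated query FASTA.

    Headers carry ``sample=<id> primer=<id> weight=<int>`` key=value tokens in
    the description, e.g. ``>q1 sample=lake1.e01.r1 primer=primer01 weight=500``.
    """
    queries = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        meta = dict(
            tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok
        )
        for need in ("sample", "primer"):
            if need not in meta:
                raise ValueError(f"query {rec.id}: header missing '{need}=' annotation")
        queries.append(
            QueryRecord(
                query_id=rec.id,
                sequence=str(rec.seq),
                sample_id=meta["sample"],
                primer_id=meta["primer"],
                weight=int(meta.get("weight", 1)),
            )
        )
    if not queries:
        raise ValueError("empty query FASTA")
    return queries
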