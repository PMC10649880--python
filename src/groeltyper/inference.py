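"""Protein grouping, Top Rank Count filtering, and taxonomy inference.

A detected peptide usually matches several database proteins (the protein
inference problem).  Proteins with an *identical* set of detected peptides
are indistinguishable and are merged into a protein group.  Groups are sorted
by the number of detected peptides, and each group's **Top Rank Count (TRC)**
is the number of its detected peptides that do not occur in any group with
strictly more peptides.  Groups with TRC below a threshold (default 5) are
discarded as likely false positives; surviving groups are assigned the most
frequent taxon name among their member proteins and merged into taxonomic
groups at the rank of interest.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import pandas as pd

from .reference_db import RANKS, UNCLASSIFIED, GroELRecord, PeptideIndex

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinGroup:
    """Database proteins sharing an identical detected-peptide set."""

    member_accessions: tuple[str, ...]
    detected_peptides: frozenset[str]
    top_rank_count: int = 0
    rank_position: int = 0

    @property
    def size(self) -> int:
        return len(self.detected_peptides)


@dataclass(frozen=True)
class TaxonCall:
    """Modal taxon of a protein group at one rank."""

    rank: str
    name: str
    frequency: float
    ambiguous: bool = False


@dataclass(frozen=True)
class TaxonGroup:
    """Protein groups merged under one modal taxon name."""

    name: str
    groups: tuple[ProteinGroup, ...]
    peptides: frozenset[str]


def match_peptides(
    peptides: Iterable[str], index: PeptideIndex
) -> tuple[dict[str, frozenset[str]], list[str]]:
    """Assign detected canonical peptides to database proteins.

    Returns the assignment map (peptide -> accession set) and the list of
    peptides with no database match, which are excluded from inference.
    """
    matched: dict[str, frozenset[str]] = {}
    unmatched: list[str] = []
    for pep in peptides:
        accs = index.get(pep)
        if accs:
            matched[pep] = accs
        else:
            unmatched.append(pep)
    if unmatched:
        logger.info(
            "%d of %d detected peptides had no database match",
            len(unmatched),
            len(matched) + len(unmatched),
        )
    return matched, unmatched


def build_protein_groups(
    assignment: Mapping[str, frozenset[str]]
) -> list[ProteinGroup]:
    """Merge proteins with identical detected-peptide sets into groups.

    Groups are sorted by number of detected peptides, descending; ties are
    ordered by the lexicographically smallest member accession (reporting
    order only — the TRC is insensitive to order among equal-size groups).
    """
    by_protein: dict[str, set[str]] = {}
    for pep, accessions in assignment.items():
        for acc in accessions:
            by_protein.setdefault(acc, set()).add(pep)
    by_pepset: dict[frozenset[str], list[str]] = {}
    for acc, peps in by_protein.items():
        by_pepset.setdefault(frozenset(peps), []).append(acc)
    groups = [
        ProteinGroup(tuple(sorted(accs)), peps) for peps, accs in by_pepset.items()
    ]
    groups.sort(key=lambda g: (-g.size, g.member_accessions[0]))
    return [replace(g, rank_position=i + 1) for i, g in enumerate(groups)]


def compute_top_rank_count(groups: list[ProteinGroup]) -> list[ProteinGroup]:
    """Top Rank Count: per group, the number of its detected peptides absent
    from every group with *strictly* more detected peptides.

    Groups of equal size do not suppress each other's peptides, so a peptide
    shared only between equal-size groups counts for both.
    """
    max_size: dict[str, int] = {}
    for g in groups:
        for pep in g.detected_peptides:
            if g.size > max_size.get(pep, 0):
                max_size[pep] = g.size
    return [
        replace(
            g,
            top_rank_count=sum(
                1 for pep in g.detected_peptides if max_size[pep] == g.size
            ),
        )
        for g in groups
    ]


def filter_by_top_rank(
    groups: list[ProteinGroup], threshold: int = 5
) -> list[ProteinGroup]:
    """Keep groups with ``top_rank_count >= threshold`` (inclusive)."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return [g for g in groups if g.top_rank_count >= threshold]


def infer_group_taxonomy(
    group: ProteinGroup, records_by_accession: Mapping[str, GroELRecord], rank: str
) -> TaxonCall:
    """Most frequent taxon name among a group's member proteins at one rank.

    Unclassified members do not vote but stay in the frequency denominator,
    so the frequency reflects agreement over all members.  If every member is
    unclassified the call is (``unclassified``, 1.0).  Ties go to the
    lexicographically smaller name and set the ambiguity flag.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    names = []
    for acc in group.member_accessions:
        try:
            names.append(records_by_accession[acc].name_at(rank))
        except KeyError:
            raise KeyError(f"unknown accession {acc!r} in protein group") from None
    votes = Counter(n for n in names if n != UNCLASSIFIED)
    if not votes:
        return TaxonCall(rank, UNCLASSIFIED, 1.0)
    top_count = max(votes.values())
    winners = sorted(n for n, c in votes.items() if c == top_count)
    return TaxonCall(
        rank, winners[0], top_count / len(names), ambiguous=len(winners) > 1
    )


def merge_into_taxa(
    groups: list[ProteinGroup],
    records_by_accession: Mapping[str, GroELRecord],
    rank: str,
) -> dict[str, TaxonGroup]:
    """Merge filtered protein groups into taxonomic groups keyed by their
    modal name; each taxonomic group carries the union of detected peptides."""
    by_name: dict[str, list[ProteinGroup]] = {}
    for g in groups:
        call = infer_group_taxonomy(g, records_by_accession, rank)
        by_name.setdefault(call.name, []).append(g)
    return {
        name: TaxonGroup(
            name,
            tuple(members),
            frozenset().union(*(g.detected_peptides for g in members)),
        )
        for name, members in by_name.items()
    }


def group_report(
    groups: list[ProteinGroup],
    records_by_accession: Mapping[str, GroELRecord],
    ranks: tuple[str, ...] = RANKS[1:],
) -> pd.DataFrame:
    """Tabular report: one row per group with size, TRC, and the modal taxon
    (with frequency) at each requested rank."""
    rows = []
    for g in groups:
        row: dict[str, object] = {
            "rank_position": g.rank_position,
            "members": ";".join(g.member_accessions),
            "n_peptides": g.size,
            "top_rank_count": g.top_rank_count,
        }
        for rank in ranks:
            call = infer_group_taxonomy(g, records_by_accession, rank)
            row[rank] = call.name
            row[f"{rank}_frequency"] = call.frequency
        rows.append(row)
    return pd.DataFrame(rows)
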