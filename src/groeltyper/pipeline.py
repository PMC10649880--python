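"""End-to-end profiling: detected peptides + database -> taxon profiles."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .inference import (
    ProteinGroup,
    TaxonGroup,
    build_protein_groups,
    compute_top_rank_count,
    filter_by_top_rank,
    match_peptides,
    merge_into_taxa,
)
from .quantify import quantify_by_count, quantify_by_intensity, quantify_by_psm
from .reference_db import GroELRecord, PeptideIndex

SCHEMES = ("peptide_count", "intensity", "psm")


@dataclass
class ProfileResult:
    """Everything the profiling pipeline produces for one peptide table."""

    rank: str
    trc_threshold: int
    groups: list[ProteinGroup]
    filtered_groups: list[ProteinGroup]
    taxa: dict[str, TaxonGroup]
    profiles: dict[str, pd.DataFrame]
    unmatched_peptides: list[str] = field(default_factory=list)

    def profile(self, scheme: str = "intensity") -> pd.DataFrame:
        return self.profiles[scheme]

    def detected_taxa(self, include_unclassified: bool = False) -> set[str]:
        names = set(self.taxa)
        if not include_unclassified:
            names.discard("unclassified")
        return names


def profile_community(
    detected: pd.DataFrame,
    records: list[GroELRecord],
    index: PeptideIndex,
    rank: str = "family",
    trc_threshold: int = 5,
    schemes: tuple[str, ...] = SCHEMES,
) -> ProfileResult:
    """Run the full inference chain on one detected-peptide table.

    Steps: match peptides against the index, merge proteins with identical
    detected-peptide sets into groups, compute the Top Rank Count, filter by
    the threshold, merge surviving groups into taxonomic groups at ``rank``,
    and quantify under each requested scheme.
    """
    by_accession = {r.accession: r for r in records}
    assignment, unmatched = match_peptides(detected["peptide"].unique(), index)
    groups = compute_top_rank_count(build_protein_groups(assignment))
    filtered = filter_by_top_rank(groups, trc_threshold)
    taxa = merge_into_taxa(filtered, by_accession, rank)
    profiles: dict[str, pd.DataFrame] = {}
    for scheme in schemes:
        if scheme == "peptide_count":
            profiles[scheme] = quantify_by_count(taxa, rank)
        elif scheme == "intensity":
            profiles[scheme] = quantify_by_intensity(taxa, detected, rank)
        elif scheme == "psm":
            profiles[scheme] = quantify_by_psm(taxa, detected, rank)
        else:
            raise ValueError(f"unknown quantification scheme {scheme!r}")
    return ProfileResult(
        rank=rank,
        trc_threshold=trc_threshold,
        groups=groups,
        filtered_groups=filtered,
        taxa=taxa,
        profiles=profiles,
        unmatched_peptides=unmatched,
    )
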