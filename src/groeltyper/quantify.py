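"""Semiquantification of taxonomic groups.

Two headline schemes:

* ``peptide_count`` — the number of non-redundant detected peptides in the
  taxonomic group.  A peptide is counted once per taxon but may count for
  several taxa (shared peptides are not split).
* ``intensity`` — the sum of MS1 precursor intensities of the group's
  peptides.  The intensity of a peptide shared between taxonomic groups is
  distributed proportionally to each group's non-redundant peptide total, so
  total intensity is conserved.

A third scheme, ``psm``, applies the intensity sharing rule to spectral
counts.  Profiles are DataFrames with columns ``taxon``, ``quantity``,
``relative_abundance`` and attrs ``rank``/``scheme``.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .inference import TaxonGroup

logger = logging.getLogger(__name__)


def _as_profile(quantities: dict[str, float], scheme: str, rank: str | None) -> pd.DataFrame:
    profile = pd.DataFrame(
        {"taxon": list(quantities), "quantity": list(quantities.values())}
    ).sort_values("quantity", ascending=False, kind="stable", ignore_index=True)
    profile.attrs["scheme"] = scheme
    profile.attrs["rank"] = rank
    return relative_abundance(profile)


def quantify_by_count(
    taxa: Mapping[str, TaxonGroup], rank: str | None = None
) -> pd.DataFrame:
    """Peptide-count profile: quantity = size of the taxon's non-redundant
    detected-peptide union; a shared peptide adds one to every taxon carrying
    it."""
    quantities = {name: float(len(tg.peptides)) for name, tg in taxa.items()}
    return _as_profile(quantities, "peptide_count", rank)


def _quantify_shared(
    taxa: Mapping[str, TaxonGroup], weight_of: Mapping[str, float], scheme: str, rank: str | None
) -> pd.DataFrame:
    # Peptide totals per taxon (the count-scheme quantity) set the sharing
    # proportions; a peptide in k taxa contributes w * n_j / sum(n_i) to taxon j.
    totals = {name: len(tg.peptides) for name, tg in taxa.items()}
    carriers: dict[str, list[str]] = {}
    for name, tg in taxa.items():
        for pep in tg.peptides:
            carriers.setdefault(pep, []).append(name)
    quantities = {name: 0.0 for name in taxa}
    missing = 0
    for pep, names in carriers.items():
        weight = weight_of.get(pep)
        if weight is None:
            missing += 1
            weight = 0.0
        denom = sum(totals[n] for n in names)
        for n in names:
            quantities[n] += weight * totals[n] / denom
    if missing:
        logger.warning("%d assigned peptides had no measured value; treated as 0", missing)
    return _as_profile(quantities, scheme, rank)


def quantify_by_intensity(
    taxa: Mapping[str, TaxonGroup], detected: pd.DataFrame, rank: str | None = None
) -> pd.DataFrame:
    """Summed-precursor-intensity profile with proportional sharing.

    ``detected`` is a detected-peptide table (any number of samples; rows for
    the same peptide are summed first).
    """
    weight_of = detected.groupby("peptide")["intensity"].sum().to_dict()
    return _quantify_shared(taxa, weight_of, "intensity", rank)


def quantify_by_psm(
    taxa: Mapping[str, TaxonGroup], detected: pd.DataFrame, rank: str | None = None
) -> pd.DataFrame:
    """Spectral-count (PSM) profile using the same proportional sharing rule
    as the intensity scheme."""
    weight_of = detected.groupby("peptide")["spectral_count"].sum().to_dict()
    return _quantify_shared(taxa, weight_of, "psm", rank)


def relative_abundance(profile: pd.DataFrame) -> pd.DataFrame:
    """Normalize raw quantities to relative abundances summing to one.

    A zero (or empty) total yields all-zero abundances and sets the
    ``zero_total`` attr instead of raising.
    """
    profile = profile.copy()
    total = float(profile["quantity"].sum()) if len(profile) else 0.0
    if total > 0:
        profile["relative_abundance"] = profile["quantity"] / total
        profile.attrs["zero_total"] = False
    else:
        profile["relative_abundance"] = 0.0
        profile.attrs["zero_total"] = True
    return profile
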