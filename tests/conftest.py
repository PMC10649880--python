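import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from groeltyper import (
    GroELRecord,
    SimParams,
    build_peptide_index,
    contaminant_peptides,
    remove_contaminants,
    simulate_community,
)

RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus")


def make_record(accession, sequence, genus="unclassified", family="unclassified",
                order="unclassified", cls="unclassified", phylum="unclassified",
                kingdom="Bacteria", **kw):
    return GroELRecord(
        accession, sequence, (kingdom, phylum, cls, order, family, genus), **kw
    )


@pytest.fixture(scope="session")
def toy_records():
    """Six proteins, three families, engineered peptide sharing."""
    shared = "TTTTTTK"  # in every protein
    recs = [
        make_record("A1", f"AAAAAAK{shared}CCCCCCK", genus="GenA1", family="FamA",
                    order="Ord1", cls="Cls1", phylum="Phy1"),
        make_record("A2", f"AAAAAAK{shared}DDDDDDK", genus="GenA2", family="FamA",
                    order="Ord1", cls="Cls1", phylum="Phy1"),
        make_record("B1", f"EEEEEEK{shared}FFFFFFK", genus="GenB1", family="FamB",
                    order="Ord1", cls="Cls1", phylum="Phy1"),
        make_record("B2", f"EEEEEEK{shared}GGGGGGK", genus="GenB2", family="FamB",
                    order="Ord1", cls="Cls1", phylum="Phy1"),
        make_record("C1", f"HHHHHHK{shared}MMMMMMK", genus="GenC1", family="FamC",
                    order="Ord2", cls="Cls2", phylum="Phy2"),
        make_record("C2", f"HHHHHHK{shared}NNNNNNK", genus="GenC2", family="FamC",
                    order="Ord2", cls="Cls2", phylum="Phy2"),
    ]
    return recs


@pytest.fixture(scope="session")
def toy_index(toy_records):
    return build_peptide_index(toy_records)


@pytest.fixture(scope="session")
def sim():
    """One simulated 12-family community, shared across tests.

    Returns (params, records, index, truth, detected-after-decontamination).
    """
    params = SimParams(seed=11)
    records, index, truth, detected = simulate_community(params)
    crap = contaminant_peptides(records, params.detect_params)
    clean = remove_contaminants(detected, crap)
    return params, records, index, truth, clean


@pytest.fixture()
def detected_frame():
    def _make(rows):
        return pd.DataFrame(rows, columns=["sample", "peptide", "intensity", "spectral_count"])

    return _make
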