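"""Seeded synthetic GroEL databases, communities, and detection tables.

The generator produces the three things the pipeline consumes, without any
downloads: a tree-consistent taxonomy with GroEL-like protein sequences, a
ground-truth community (taxon, relative protein share), and a detected-
peptide table emulating the peptide-centric output of an MS search.

Sequences descend from one ancestral protein by rank-scaled random
substitution, so peptide sharing decreases with taxonomic distance — the
property that makes tryptic GroEL peptides taxon-specific in the first
place.  Detection samples each taxon's tryptic peptides (6-40 residues, the
identification window of a typical search) with a probability scaled by the
taxon's protein share, assigns log-normal MS1 intensities scaled by the
share, and adds decoy peptides (absent from the database, emulating search
false positives) and contaminant peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import COLUMNS, aggregate_duplicates
from .digest import DETECTION_DIGEST, DigestParams, canonicalize_peptide, digest_trypsin
from .reference_db import RANKS, GroELRecord, PeptideIndex, build_peptide_index

# Amino-acid alphabet with roughly natural bacterial frequencies; K and R
# together ~11% so tryptic peptides of 6-40 residues are plentiful.
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_FREQ = np.array(
    [
        0.089, 0.011, 0.054, 0.062, 0.039, 0.078, 0.021, 0.066, 0.058, 0.098,
        0.024, 0.041, 0.044, 0.038, 0.055, 0.059, 0.054, 0.071, 0.012, 0.026,
    ]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

_TREE_RANKS = RANKS[1:]  # kingdom is constant ("Bacteria")


@dataclass(frozen=True)
class SimParams:
    """Synthetic-community generator settings.

    The taxonomy counts give a tree of 12 families by default (a balanced
    mock-community scale); ``substitution_rate_per_rank`` sets the fraction
    of residues replaced on the branch entering each level, higher between
    phyla than within genera, and ``protein`` is the within-genus divergence
    between paralogues/strains.  Intensities are log-normal in natural-log
    space (exp(16) ~ 9e6, a typical MS1 precursor magnitude).
    """

    n_phyla: int = 4
    n_classes: int = 6
    n_orders: int = 8
    n_families: int = 12
    n_genera: int = 24
    proteins_per_genus: int = 3
    protein_length: int = 540
    substitution_rate_per_rank: dict[str, float] = field(
        default_factory=lambda: {
            "phylum": 0.25,
            "class": 0.18,
            "order": 0.13,
            "family": 0.09,
            "genus": 0.05,
            "protein": 0.01,
        }
    )
    detect_params: DigestParams = DETECTION_DIGEST
    detection_prob: float = 0.6
    detection_floor: float = 0.02
    intensity_lognormal_params: tuple[float, float] = (16.0, 1.0)
    n_contaminants: int = 5
    contaminant_fraction: float = 0.02
    false_peptide_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_phyla, self.n_classes, self.n_orders, self.n_families,
                  self.n_genera, self.proteins_per_genus)
        if any(c < 1 for c in counts):
            raise ValueError("all taxonomy counts must be >= 1")
        for p in (self.detection_prob, self.detection_floor,
                  self.contaminant_fraction, self.false_peptide_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities and fractions must lie in [0, 1]")


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_AA, size=length, p=_AA_FREQ))


def _mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute round(rate * len) positions with fresh residues."""
    n_sub = int(round(rate * len(sequence)))
    if n_sub == 0:
        return sequence
    seq = np.array(list(sequence))
    positions = rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False)
    seq[positions] = rng.choice(_AA, size=len(positions), p=_AA_FREQ)
    return "".join(seq)


def generate_taxonomy(params: SimParams) -> pd.DataFrame:
    """Tree-consistent lineage table, one row per genus.

    Children are distributed over parents round-robin, so each class belongs
    to exactly one phylum, each order to one class, and so on.  Deterministic
    given the parameters (no randomness is needed for the tree shape).
    """
    counts = {
        "phylum": params.n_phyla,
        "class": params.n_classes,
        "order": params.n_orders,
        "family": params.n_families,
        "genus": params.n_genera,
    }
    names = {
        rank: [f"{rank.capitalize()}_{i + 1:02d}" for i in range(n)]
        for rank, n in counts.items()
    }
    parent_rank = dict(zip(_TREE_RANKS[1:], _TREE_RANKS[:-1]))
    parent_of: dict[str, str] = {}
    for rank in _TREE_RANKS[1:]:
        up = parent_rank[rank]
        for i, child in enumerate(names[rank]):
            parent_of[child] = names[up][i % counts[up]]
    rows = []
    for genus in names["genus"]:
        lineage = {"genus": genus}
        for rank in reversed(_TREE_RANKS[:-1]):
            child_rank = _TREE_RANKS[_TREE_RANKS.index(rank) + 1]
            lineage[rank] = parent_of[lineage[child_rank]]
        rows.append({"kingdom": "Bacteria", **{r: lineage[r] for r in _TREE_RANKS}})
    return pd.DataFrame(rows, columns=list(RANKS))


def generate_sequences(
    taxonomy: pd.DataFrame, params: SimParams
) -> list[GroELRecord]:
    """GroEL-like records: one ancestral sequence mutated down the tree.

    Each taxon's sequence is its parent's sequence with ``rate * length``
    random substitutions, so within-genus proteins share most tryptic
    peptides while different families share few.
    """
    rng = np.random.default_rng(params.seed)
    rates = params.substitution_rate_per_rank
    ancestor = _random_sequence(params.protein_length, rng)
    seq_of: dict[tuple[str, str], str] = {}
    for rank in _TREE_RANKS:
        parent_rank_idx = _TREE_RANKS.index(rank) - 1
        for _, row in taxonomy.drop_duplicates(subset=[rank]).iterrows():
            key = (rank, row[rank])
            if key in seq_of:
                continue
            if parent_rank_idx < 0:
                base = ancestor
            else:
                base = seq_of[(_TREE_RANKS[parent_rank_idx], row[_TREE_RANKS[parent_rank_idx]])]
            seq_of[key] = _mutate(base, rates[rank], rng)
    records = []
    for _, row in taxonomy.iterrows():
        genus_seq = seq_of[("genus", row["genus"])]
        lineage = tuple(row[r] for r in RANKS)
        for j in range(params.proteins_per_genus):
            seq = _mutate(genus_seq, rates["protein"], rng)
            records.append(GroELRecord(f"SIM_{row['genus']}_{j + 1}", seq, lineage))
    return records


def generate_contaminants(params: SimParams) -> list[GroELRecord]:
    """Random contaminant proteins (a stand-in for a cRAP list), flagged and
    unclassified."""
    rng = np.random.default_rng(params.seed + 1_000_003)
    return [
        GroELRecord(
            f"CONTAM_{i + 1:03d}",
            _random_sequence(params.protein_length, rng),
            is_contaminant=True,
        )
        for i in range(params.n_contaminants)
    ]


def community_shares(
    taxa: list[str], profile: str = "balanced", rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Ground-truth community table (taxon, share).

    ``balanced`` ramps shares linearly from 4.8 to 19.1 (the spread of a
    well-balanced mock community) before normalizing to 1; ``skewed`` uses a
    geometric ramp spanning roughly 0.2-40% to emulate an uneven community;
    ``uniform`` gives equal shares.
    """
    n = len(taxa)
    if profile == "balanced":
        raw = np.linspace(4.8, 19.1, n) if n > 1 else np.array([1.0])
    elif profile == "skewed":
        raw = np.geomspace(0.2, 41.8, n) if n > 1 else np.array([1.0])
    elif profile == "uniform":
        raw = np.ones(n)
    else:
        raise ValueError(f"unknown share profile {profile!r}")
    if rng is not None:
        raw = rng.permutation(raw)
    return pd.DataFrame({"taxon": taxa, "share": raw / raw.sum()})


def _detection_probability(share: float, mean_share: float, params: SimParams) -> float:
    # Abundance-dependent sampling with a fixed floor so that rare taxa lose
    # peptides gradually instead of all-or-nothing.
    scaled = params.detection_prob * (0.3 + 0.7 * share / mean_share)
    return float(np.clip(scaled, params.detection_floor, 1.0))


def _random_tryptic_like(rng: np.random.Generator) -> str:
    length = int(rng.integers(7, 21))
    body = "".join(rng.choice(_AA, size=length - 1, p=_AA_FREQ)).replace("K", "A").replace("R", "G")
    return body + ("K" if rng.random() < 0.5 else "R")


def simulate_detection(
    records: list[GroELRecord],
    community: pd.DataFrame,
    params: SimParams,
    rank: str = "family",
    contaminant_peptide_pool: set[str] | None = None,
    sample_id: str = "sim",
) -> pd.DataFrame:
    """Simulate the peptide-centric output of an MS search for a community.

    For each taxon with share > 0, every canonical tryptic peptide of its
    proteins (within the detection length window) is observed independently
    with a share-scaled probability and given a log-normal intensity scaled
    by the share.  Decoy peptides absent from the database and contaminant
    peptides are mixed in.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed + 7)
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    pool: dict[str, set[str]] = {}
    for rec in records:
        if rec.is_contaminant:
            continue
        peps = {
            canonicalize_peptide(p)
            for p in digest_trypsin(rec.sequence, params.detect_params)
        }
        pool.setdefault(rec.name_at(rank), set()).update(peps)
    db_peptides = set().union(*pool.values()) if pool else set()
    missing = set(community["taxon"]) - set(pool)
    if missing:
        raise ValueError(f"community taxa absent from database: {sorted(missing)}")

    mu, sigma = params.intensity_lognormal_params
    shares = community.set_index("taxon")["share"]
    positive = shares[shares > 0]
    mean_share = float(positive.mean()) if len(positive) else 1.0
    rows: list[tuple[str, str, float, int]] = []
    for taxon, share in shares.items():
        if share <= 0:
            continue
        p_detect = _detection_probability(float(share), mean_share, params)
        for pep in sorted(pool[taxon]):
            if rng.random() < p_detect:
                intensity = float(share) * float(rng.lognormal(mu, sigma))
                rows.append((sample_id, pep, intensity, 1))

    n_true = len(rows)
    n_false = int(round(params.false_peptide_fraction * n_true))
    made = 0
    while made < n_false:
        decoy = canonicalize_peptide(_random_tryptic_like(rng))
        if decoy in db_peptides or len(decoy) < params.detect_params.min_len:
            continue
        rows.append((sample_id, decoy, mean_share * float(rng.lognormal(mu, sigma)), 1))
        made += 1
    if contaminant_peptide_pool:
        n_contam = int(round(params.contaminant_fraction * n_true))
        contams = sorted(contaminant_peptide_pool)
        for idx in rng.choice(len(contams), size=min(n_contam, len(contams)), replace=False):
            rows.append(
                (sample_id, contams[idx], mean_share * float(rng.lognormal(mu, sigma)), 1)
            )
    detected = pd.DataFrame(rows, columns=COLUMNS)
    return aggregate_duplicates(detected)


def simulate_community(
    params: SimParams,
    rank: str = "family",
    share_profile: str = "balanced",
) -> tuple[list[GroELRecord], PeptideIndex, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: database, index, ground truth, detected table.

    The community spans every taxon of the database at ``rank``; contaminant
    peptides are simulated into the detected table and must be removed with
    :func:`groeltyper.detection.remove_contaminants` before inference (see
    :func:`groeltyper.reference_db.contaminant_peptides`).
    """
    taxonomy = generate_taxonomy(params)
    records = generate_sequences(taxonomy, params) + generate_contaminants(params)
    index = build_peptide_index(records)
    taxa = sorted(taxonomy[rank].unique())
    truth = community_shares(taxa, share_profile)
    from .reference_db import contaminant_peptides as _crap

    crap = _crap(records, params.detect_params)
    detected = simulate_detection(
        records, truth, params, rank=rank, contaminant_peptide_pool=crap
    )
    return records, index, truth, detected
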