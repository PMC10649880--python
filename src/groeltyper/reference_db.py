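"""GroEL marker database: records, peptide index, taxonomy, serialization.

The database holds one record per GroEL protein (accession, amino-acid
sequence, six-rank lineage) plus appended contaminant proteins.  From the
records a peptide index is derived: a map from every canonicalized tryptic
peptide to the set of accessions whose digest contains it.  Taxon names are
standardized against a registry of validly published names (LPSN-style);
names absent from the registry are replaced by the ``unclassified`` sentinel.

Serialization follows the two-file layout used by peptide-centric search
workflows: a FASTA of protein sequences (search-engine input, contaminants
included) and a nine-column TSV used for protein and taxonomy inference
(accession, sequence, expected tryptic peptides, kingdom...genus;
contaminants are kept out of the inference TSV — their peptides form a
separate exclusion list).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digest import DigestParams, canonicalize_peptide, digest_trypsin

logger = logging.getLogger(__name__)

#: Taxonomic ranks carried by every record, coarsest to finest.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

#: Sentinel for a missing or non-validated taxon name.  Written as an empty
#: cell in TSV files.
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class GroELRecord:
    """One database protein: accession, sequence, six-rank lineage."""

    accession: str
    sequence: str
    lineage: tuple[str, ...] = (UNCLASSIFIED,) * len(RANKS)
    is_contaminant: bool = False

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        if len(self.lineage) != len(RANKS):
            raise ValueError(
                f"{self.accession}: lineage must have {len(RANKS)} rank slots"
            )

    def name_at(self, rank: str) -> str:
        return self.lineage[RANKS.index(rank)]


@dataclass
class PeptideIndex:
    """Map canonical tryptic peptide -> set of accessions containing it."""

    entries: dict[str, frozenset[str]] = field(default_factory=dict)
    params: DigestParams = field(default_factory=DigestParams)

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.entries

    def __getitem__(self, peptide: str) -> frozenset[str]:
        return self.entries[peptide]

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, peptide: str, default=None):
        return self.entries.get(peptide, default)


# ---------------------------------------------------------------------------
# Loading


def _pad_lineage(names: list[str]) -> tuple[str, ...]:
    names = [n.strip() if n and n.strip() else UNCLASSIFIED for n in names]
    names += [UNCLASSIFIED] * (len(RANKS) - len(names))
    return tuple(names[: len(RANKS)])


def _check_unique(records: list[GroELRecord]) -> list[GroELRecord]:
    seen: set[str] = set()
    for rec in records:
        if rec.accession in seen:
            raise ValueError(f"duplicate accession {rec.accession!r}")
        seen.add(rec.accession)
    return records


def load_records(source: str | Path) -> list[GroELRecord]:
    """Load GroEL records from FASTA (``lineage=k;p;c;o;f;g`` in the header
    description) or from a TSV with ``accession``, ``sequence`` and rank
    columns.  Missing lineage slots default to ``unclassified``; records with
    an empty sequence are skipped with a warning; duplicate accessions are a
    hard error.
    """
    path = Path(source)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        return _load_records_fasta(path)
    return _load_records_tsv(path)


def _load_records_fasta(path: Path) -> list[GroELRecord]:
    records: list[GroELRecord] = []
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        seq = str(seq_rec.seq).strip()
        if not seq:
            logger.warning("skipping %s: empty sequence", seq_rec.id)
            continue
        lineage = (UNCLASSIFIED,) * len(RANKS)
        for token in seq_rec.description.split():
            if token.startswith("lineage="):
                lineage = _pad_lineage(token[len("lineage=") :].split(";"))
        records.append(GroELRecord(seq_rec.id, seq, lineage))
    return _check_unique(records)


def _load_records_tsv(path: Path) -> list[GroELRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("accession", "sequence"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path}")
    records: list[GroELRecord] = []
    for row in df.to_dict("records"):  # 'class' is a keyword; avoid itertuples
        seq = row["sequence"].strip()
        if not seq:
            logger.warning("skipping %s: empty sequence", row["accession"])
            continue
        lineage = _pad_lineage([row.get(r, "") for r in RANKS])
        records.append(GroELRecord(row["accession"], seq, lineage))
    return _check_unique(records)


def load_registry(path: str | Path) -> dict[str, set[str]]:
    """Load a taxon-name registry from a two-column TSV (rank, name).

    Names are stored case-folded and whitespace-trimmed; matching during
    standardization uses the same normalization.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["rank", "name"]:
        raise ValueError("registry must have columns 'rank' and 'name'")
    registry: dict[str, set[str]] = {rank: set() for rank in RANKS}
    for row in df.itertuples(index=False):
        rank = row.rank.strip().lower()
        if rank not in registry:
            raise ValueError(f"unknown rank {row.rank!r} in registry")
        registry[rank].add(row.name.strip().casefold())
    return registry


# ---------------------------------------------------------------------------
# Filtering and deduplication


def filter_by_length(
    records: list[GroELRecord], min_aa: int = 6, max_aa: int = 1500
) -> list[GroELRecord]:
    """Keep records whose sequence length lies in [min_aa, max_aa] (inclusive)."""
    kept = [r for r in records if min_aa <= len(r.sequence) <= max_aa]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter_by_length removed %d of %d records", removed, len(records))
    return kept


def deduplicate_sequences(records: list[GroELRecord]) -> dict[str, list[str]]:
    """Exact-string protein deduplication: sequence -> member accessions.

    No I/L folding at the protein level; isobaric indistinguishability applies
    only to peptides, not proteins.
    """
    dedup: dict[str, list[str]] = {}
    for rec in records:
        dedup.setdefault(rec.sequence, []).append(rec.accession)
    return dedup


# ---------------------------------------------------------------------------
# Taxonomy standardization


def standardize_taxonomy(
    records: list[GroELRecord], registry: dict[str, set[str]]
) -> list[GroELRecord]:
    """Replace lineage names not present in the registry by ``unclassified``.

    Matching is exact after whitespace trimming and case folding; no fuzzy
    matching.  An empty registry for a rank blanks that rank for all records
    (with a warning).
    """
    for rank in RANKS:
        if not registry.get(rank):
            logger.warning("registry has no names for rank %r", rank)
    out = []
    for rec in records:
        lineage = tuple(
            name.strip()
            if name.strip().casefold() in registry.get(rank, set())
            else UNCLASSIFIED
            for rank, name in zip(RANKS, rec.lineage)
        )
        out.append(replace(rec, lineage=lineage) if lineage != rec.lineage else rec)
    return out


# ---------------------------------------------------------------------------
# Peptide index and specificity statistics


def build_peptide_index(
    records: list[GroELRecord], params: DigestParams = DigestParams()
) -> PeptideIndex:
    """Digest all non-contaminant records and index canonical peptides.

    Each index key is an I/L-folded tryptic peptide; its value is the union
    of accessions of every protein whose digest contains that peptide.
    Identical protein sequences are digested once.
    """
    entries: dict[str, set[str]] = {}
    dedup = deduplicate_sequences([r for r in records if not r.is_contaminant])
    for sequence, accessions in dedup.items():
        for peptide in digest_trypsin(sequence, params):
            entries.setdefault(canonicalize_peptide(peptide), set()).update(accessions)
    return PeptideIndex(
        {pep: frozenset(accs) for pep, accs in entries.items()}, params
    )


def contaminant_peptides(
    records: list[GroELRecord], params: DigestParams = DigestParams()
) -> set[str]:
    """Canonical tryptic peptides of all contaminant-flagged records."""
    out: set[str] = set()
    for rec in records:
        if rec.is_contaminant:
            out.update(
                canonicalize_peptide(p) for p in digest_trypsin(rec.sequence, params)
            )
    return out


def taxon_specific_counts(
    index: PeptideIndex, records: list[GroELRecord], rank: str
) -> dict[str, int]:
    """Standardized and taxon-specific peptide counts at one rank.

    A peptide is *standardized* at a rank when every protein containing it
    carries a validated (non-``unclassified``) name at that rank, and
    *taxon-specific* when those names are all identical — i.e. the peptide is
    exclusively attributable to a single taxon.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    name_of = {rec.accession: rec.name_at(rank) for rec in records}
    standardized = specific = 0
    for accessions in index.entries.values():
        names = {name_of[acc] for acc in accessions}
        if UNCLASSIFIED in names:
            continue
        standardized += 1
        if len(names) == 1:
            specific += 1
    return {
        "rank": rank,
        "standardized_peptides": standardized,
        "taxon_specific_peptides": specific,
    }


def specificity_table(
    index: PeptideIndex, records: list[GroELRecord], ranks: tuple[str, ...] = RANKS[1:]
) -> pd.DataFrame:
    """Per-rank specificity statistics (phylum...genus by default)."""
    rows = [taxon_specific_counts(index, records, rank) for rank in ranks]
    df = pd.DataFrame(rows)
    df["total_nonredundant_peptides"] = len(index)
    return df


# ---------------------------------------------------------------------------
# Contaminants and serialization


def append_contaminants(
    records: list[GroELRecord], crap: str | Path
) -> list[GroELRecord]:
    """Append contaminant proteins (cRAP-style FASTA) to the database.

    Contaminants are flagged and carry an all-``unclassified`` lineage; an
    accession colliding with an existing record is prefixed ``CONTAM_``.
    """
    existing = {r.accession for r in records}
    out = list(records)
    for seq_rec in SeqIO.parse(str(crap), "fasta"):
        seq = str(seq_rec.seq).strip()
        if not seq:
            logger.warning("skipping contaminant %s: empty sequence", seq_rec.id)
            continue
        acc = seq_rec.id
        if acc in existing:
            logger.warning("contaminant accession %s collides; prefixing", acc)
            acc = f"CONTAM_{acc}"
        existing.add(acc)
        out.append(GroELRecord(acc, seq, is_contaminant=True))
    return out


def write_database(
    records: list[GroELRecord],
    fasta_path: str | Path,
    tsv_path: str | Path,
    params: DigestParams = DigestParams(),
) -> None:
    """Write the search FASTA and the inference TSV.

    The FASTA contains every record, contaminants included, so it can serve
    as search-engine input.  The TSV contains the taxonomy-inference records
    only (contaminants excluded): accession, sequence, semicolon-joined
    canonical tryptic peptides, and the six lineage ranks, with
    ``unclassified`` written as an empty cell.  Output is deterministic:
    records keep input order and peptides are sorted.
    """
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")

    rows = []
    for rec in records:
        if rec.is_contaminant:
            continue
        peptides = sorted(
            {canonicalize_peptide(p) for p in digest_trypsin(rec.sequence, params)}
        )
        row = {
            "accession": rec.accession,
            "sequence": rec.sequence,
            "peptides": ";".join(peptides),
        }
        for rank, name in zip(RANKS, rec.lineage):
            row[rank] = "" if name == UNCLASSIFIED else name
        rows.append(row)
    columns = ["accession", "sequence", "peptides", *RANKS]
    pd.DataFrame(rows, columns=columns).to_csv(tsv_path, sep="\t", index=False)


def read_database(
    tsv_path: str | Path, params: DigestParams = DigestParams()
) -> tuple[list[GroELRecord], PeptideIndex]:
    """Read an inference TSV back into records and a peptide index.

    The index is reconstructed from the stored peptides column, so a written
    database round-trips without re-digestion.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["accession", "sequence", "peptides", *RANKS]
    if list(df.columns) != expected:
        raise ValueError(f"unexpected columns in {tsv_path}: {list(df.columns)}")
    records: list[GroELRecord] = []
    entries: dict[str, set[str]] = {}
    for row in df.to_dict("records"):
        lineage = _pad_lineage([row[r] for r in RANKS])
        records.append(GroELRecord(row["accession"], row["sequence"], lineage))
        if row["peptides"]:
            for pep in row["peptides"].split(";"):
                entries.setdefault(pep, set()).add(row["accession"])
    _check_unique(records)
    index = PeptideIndex({p: frozenset(a) for p, a in entries.items()}, params)
    return records, index
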