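"""Build a small GroEL marker database and inspect peptide taxon-specificity.

Constructs a toy set of chaperonin records with lineages, standardizes the
taxon names against a registry, appends a contaminant protein, writes the
search FASTA + inference TSV, and prints per-rank specificity statistics.
"""

import tempfile
from pathlib import Path

from groeltyper import (
    GroELRecord,
    append_contaminants,
    build_peptide_index,
    filter_by_length,
    load_registry,
    read_database,
    specificity_table,
    standardize_taxonomy,
    write_database,
)

workdir = Path(tempfile.mkdtemp())

records = [
    GroELRecord("T1", "AAAGGGKTTTTTTKCCCGGGK",
                ("Bacteria", "Pseudomonadota", "Betaproteobacteria",
                 "Rhodocyclales", "Zoogloeaceae", "Thauera")),
    GroELRecord("P1", "DDDGGGKTTTTTTKEEEGGGK",
                ("Bacteria", "Pseudomonadota", "Gammaproteobacteria",
                 "Pseudomonadales", "Pseudomonadaceae", "Pseudomonas")),
    GroELRecord("U1", "FFFGGGKTTTTTTKHHHGGGK",
                ("Bacteria", "Pseudomonadota", "Gammaproteobacteria",
                 "Pseudomonadales", "Pseudomonadaceae", "Candidatus Madeupus")),
    GroELRecord("SHORT", "AAK"),  # below the 6-residue protein length floor
]

registry_path = workdir / "registry.tsv"
registry_path.write_text(
    "rank\tname\n"
    + "\n".join(
        f"{rank}\t{name}"
        for rank, name in [
            ("kingdom", "Bacteria"), ("phylum", "Pseudomonadota"),
            ("class", "Betaproteobacteria"), ("class", "Gammaproteobacteria"),
            ("order", "Rhodocyclales"), ("order", "Pseudomonadales"),
            ("family", "Zoogloeaceae"), ("family", "Pseudomonadaceae"),
            ("genus", "Thauera"), ("genus", "Pseudomonas"),
        ]
    )
    + "\n"
)
crap_path = workdir / "crap.fasta"
crap_path.write_text(">KERATIN_HUMAN\nMMMMMMKPPPPPPR\n")

records = filter_by_length(records)                       # drops SHORT
records = standardize_taxonomy(records, load_registry(registry_path))
records = append_contaminants(records, crap_path)
write_database(records, workdir / "db.fasta", workdir / "db.tsv")
records, index = read_database(workdir / "db.tsv")

print(f"database: {len(records)} proteins, {len(index)} non-redundant peptides")
print("'Candidatus Madeupus' is not in the registry ->",
      records[2].name_at("genus"))
print()
print(specificity_table(index, records).to_string(index=False))
print()
print("Every protein shares TTTTTTK, so it is specific at no rank below "
      "phylum; the flanking peptides are genus-specific.")
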