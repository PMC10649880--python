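"""Marker-database construction: loading, filtering, taxonomy, index, I/O."""

import numpy as np
import pytest

from groeltyper import (
    DigestParams,
    GroELRecord,
    append_contaminants,
    build_peptide_index,
    contaminant_peptides,
    canonicalize_peptide,
    deduplicate_sequences,
    digest_trypsin,
    filter_by_length,
    load_records,
    load_registry,
    read_database,
    specificity_table,
    standardize_taxonomy,
    taxon_specific_counts,
    write_database,
)
from conftest import make_record
from oracles import oracle_digest

AA = list("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# Loading


def test_load_records_tsv_roundtrip_and_defaults(tmp_path):
    path = tmp_path / "records.tsv"
    path.write_text(
        "accession\tsequence\tkingdom\tphylum\tclass\torder\tfamily\tgenus\n"
        "A1\tAAAAAAK\tBacteria\tP\tC\tO\tF\tThauera\n"
        "A2\tCCCCCCK\tBacteria\tP\tC\tO\tF\t\n"  # missing genus
        "A3\t\tBacteria\tP\tC\tO\tF\tG\n"  # empty sequence -> skipped
    )
    records = load_records(path)
    assert [r.accession for r in records] == ["A1", "A2"]
    assert records[0].name_at("genus") == "Thauera"
    assert records[1].name_at("genus") == "unclassified"


def test_load_records_fasta_with_lineage(tmp_path):
    path = tmp_path / "records.fasta"
    path.write_text(
        ">A1 lineage=Bacteria;P;C;O;F;G\nAAAAAAK\n>A2\nCCCCCCK\n"
    )
    records = load_records(path)
    assert records[0].lineage == ("Bacteria", "P", "C", "O", "F", "G")
    assert records[1].lineage == ("unclassified",) * 6


def test_duplicate_accession_is_hard_error(tmp_path):
    path = tmp_path / "dup.fasta"
    path.write_text(">A1\nAAAAAAK\n>A1\nCCCCCCK\n")
    with pytest.raises(ValueError, match="duplicate accession"):
        load_records(path)


# ---------------------------------------------------------------------------
# Length filter and deduplication


def test_filter_by_length_bounds_inclusive():
    records = [make_record(f"R{n}", "A" * n) for n in (5, 6, 1500, 1501)]
    kept = filter_by_length(records)
    assert [len(r.sequence) for r in kept] == [6, 1500]


def test_filter_by_length_matches_per_record_check():
    rng = np.random.default_rng(5)
    records = [
        make_record(f"R{i}", "A" * int(rng.integers(1, 2001))) for i in range(10)
    ]
    kept = filter_by_length(records)
    assert kept == [r for r in records if 6 <= len(r.sequence) <= 1500]


def test_deduplicate_exact_string_no_il_folding():
    records = [
        make_record("X1", "AAILAAK"),
        make_record("X2", "AAILAAK"),
        make_record("X3", "AALLAAK"),  # I/L variant stays a separate protein
    ]
    dedup = deduplicate_sequences(records)
    assert dedup == {"AAILAAK": ["X1", "X2"], "AALLAAK": ["X3"]}


def test_deduplicate_matches_nested_loop_oracle():
    rng = np.random.default_rng(9)
    pool = ["".join(rng.choice(AA, size=12)) for _ in range(6)]
    records = [
        make_record(f"R{i}", pool[int(rng.integers(len(pool)))]) for i in range(30)
    ]
    dedup = deduplicate_sequences(records)
    for seq, accs in dedup.items():
        assert accs == [r.accession for r in records if r.sequence == seq]
    assert sum(len(a) for a in dedup.values()) == len(records)


# ---------------------------------------------------------------------------
# Taxonomy standardization


def test_standardize_keeps_registry_names_and_blanks_others(tmp_path):
    reg_path = tmp_path / "registry.tsv"
    reg_path.write_text("rank\tname\ngenus\tThauera\nfamily\tZoogloeaceae\n")
    registry = load_registry(reg_path)
    records = [
        make_record("A", "AAAAAAK", genus="Thauera", family="Zoogloeaceae"),
        make_record("B", "AAAAAAK", genus="Candidatus Foo", family="zoogloeaceae "),
    ]
    out = standardize_taxonomy(records, registry)
    assert out[0].name_at("genus") == "Thauera"
    assert out[1].name_at("genus") == "unclassified"
    # case-insensitive, whitespace-trimmed match keeps the record's spelling
    assert out[1].name_at("family") == "zoogloeaceae"
    # phylum registry is empty -> everything unclassified there
    assert all(r.name_at("phylum") == "unclassified" for r in out)


def test_standardize_membership_matches_brute_force():
    registry = {r: set() for r in ("kingdom", "phylum", "class", "order", "family", "genus")}
    registry["genus"] = {"alpha", "beta"}
    names = ["Alpha", "beta", "Gamma", " alpha ", "BETA", "delta"]
    records = [make_record(f"R{i}", "AAAAAAK", genus=n) for i, n in enumerate(names)]
    out = standardize_taxonomy(records, registry)
    for rec, name in zip(out, names):
        expected = name.strip() if name.strip().casefold() in registry["genus"] else "unclassified"
        assert rec.name_at("genus") == expected


# ---------------------------------------------------------------------------
# Peptide index


def test_index_shared_peptides_union_accessions(toy_records, toy_index):
    shared = canonicalize_peptide("TTTTTTK")
    assert toy_index[shared] == frozenset(r.accession for r in toy_records)
    assert toy_index[canonicalize_peptide("CCCCCCK")] == frozenset({"A1"})


def test_index_folds_il_variants_to_one_key():
    records = [make_record("P1", "AAIAAAK"), make_record("P2", "AALAAAK")]
    index = build_peptide_index(records)
    assert index["AALAAAK"] == frozenset({"P1", "P2"})
    assert "AAIAAAK" not in index


def test_index_matches_containment_oracle():
    rng = np.random.default_rng(21)
    records = [
        make_record(f"R{i}", "".join(rng.choice(AA, size=60))) for i in range(5)
    ]
    index = build_peptide_index(records)
    # brute force: digest every protein with the oracle and scan
    expected: dict[str, set[str]] = {}
    for rec in records:
        for pep in oracle_digest(rec.sequence):
            expected.setdefault(canonicalize_peptide(pep), set()).add(rec.accession)
    assert {k: set(v) for k, v in index.entries.items()} == expected


# ---------------------------------------------------------------------------
# Taxon specificity


def test_single_genus_database_all_peptides_genus_specific():
    records = [
        make_record("A", "AADDEEKAAFFGGK", genus="G1", family="F1"),
        make_record("B", "AADDEEKAAHHMMK", genus="G1", family="F1"),
    ]
    index = build_peptide_index(records)
    row = taxon_specific_counts(index, records, "genus")
    assert row["standardized_peptides"] == len(index)
    assert row["taxon_specific_peptides"] == len(index)


def test_peptide_shared_between_genera_specific_at_family_only(toy_records, toy_index):
    # "AAAAAAK" occurs in genera GenA1 and GenA2, both family FamA
    genus = taxon_specific_counts(toy_index, toy_records, "genus")
    family = taxon_specific_counts(toy_index, toy_records, "family")
    pep = canonicalize_peptide("AAAAAAK")
    assert toy_index[pep] == frozenset({"A1", "A2"})
    assert family["taxon_specific_peptides"] > genus["taxon_specific_peptides"]


def test_specificity_table_matches_exhaustive_check(toy_records, toy_index):
    table = specificity_table(toy_index, toy_records)
    for _, row in table.iterrows():
        rank = row["rank"]
        std = spec = 0
        for pep, accs in toy_index.entries.items():
            names = {r.name_at(rank) for r in toy_records if r.accession in accs}
            if "unclassified" not in names:
                std += 1
                spec += len(names) == 1
        assert row["standardized_peptides"] == std
        assert row["taxon_specific_peptides"] == spec


def test_unknown_rank_is_hard_error(toy_records, toy_index):
    with pytest.raises(ValueError):
        taxon_specific_counts(toy_index, toy_records, "species")


# ---------------------------------------------------------------------------
# Contaminants and serialization


def test_append_contaminants_flags_and_collision(tmp_path, toy_records):
    crap = tmp_path / "crap.fasta"
    crap.write_text(">KERATIN\nMMMMMMKAAAAAAR\n>A1\nPPPPPPK\n")
    out = append_contaminants(toy_records, crap)
    assert len(out) == len(toy_records) + 2
    added = out[len(toy_records):]
    assert all(r.is_contaminant for r in added)
    assert added[1].accession == "CONTAM_A1"  # collision resolved
    assert added[0].lineage == ("unclassified",) * 6
    peps = contaminant_peptides(out)
    assert canonicalize_peptide("MMMMMMK") in peps


def test_append_empty_crap_is_identity(tmp_path, toy_records):
    crap = tmp_path / "empty.fasta"
    crap.write_text("")
    assert append_contaminants(toy_records, crap) == toy_records


def test_write_read_roundtrip(tmp_path, toy_records, toy_index):
    fasta, tsv = tmp_path / "db.fasta", tmp_path / "db.tsv"
    write_database(toy_records, fasta, tsv)
    records, index = read_database(tsv)
    assert records == list(toy_records)
    assert index.entries == toy_index.entries
    # deterministic serialization
    write_database(toy_records, tmp_path / "db2.fasta", tmp_path / "db2.tsv")
    assert (tmp_path / "db2.tsv").read_bytes() == tsv.read_bytes()
    assert (tmp_path / "db2.fasta").read_bytes() == fasta.read_bytes()


def test_tsv_has_nine_columns_and_peptides_redigest(tmp_path, toy_records):
    fasta, tsv = tmp_path / "db.fasta", tmp_path / "db.tsv"
    write_database(toy_records, fasta, tsv)
    lines = tsv.read_text().strip().split("\n")
    assert all(len(line.split("\t")) == 9 for line in lines)
    header, *rows = lines
    by_acc = {r.accession: r for r in toy_records}
    for line in rows:
        fields = line.split("\t")
        rec = by_acc[fields[0]]
        redigested = {
            canonicalize_peptide(p) for p in digest_trypsin(rec.sequence, DigestParams())
        }
        assert set(fields[2].split(";")) == redigested
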