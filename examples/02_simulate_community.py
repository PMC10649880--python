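"""Simulate a 12-family mock community and its detected-peptide table.

Generates a tree-consistent taxonomy, GroEL-like sequences that diverge with
taxonomic distance, a balanced ground-truth community, and a synthetic MS
peptide table with share-scaled detection, log-normal intensities, decoys and
contaminants.
"""

from groeltyper import SimParams, contaminant_peptides, simulate_community

params = SimParams(seed=42)
records, index, truth, detected = simulate_community(params)

print(f"database : {len(records)} proteins "
      f"({sum(r.is_contaminant for r in records)} contaminants), "
      f"{len(index)} indexed peptides")
print(f"community: {len(truth)} families, shares "
      f"{truth['share'].min():.3f}-{truth['share'].max():.3f} (sum "
      f"{truth['share'].sum():.0f})")
print(f"detected : {len(detected)} non-redundant peptides")
print()
print("ground truth (relative protein share per family):")
print(truth.to_string(index=False, float_format="%.4f"))
print()
crap = contaminant_peptides(records, params.detect_params)
n_crap = detected["peptide"].isin(crap).sum()
n_unmatched = (~detected["peptide"].isin(index.entries)).sum() - n_crap
print(f"{n_crap} detected rows are contaminant peptides (to be removed before "
      f"inference); ~{n_unmatched} are decoys absent from the database, "
      "emulating search false positives.")
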