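# Methods

## The profiling model

A detected tryptic peptide rarely identifies a unique protein: homologous
GroEL sequences share most of their peptides (the protein inference
problem), and a large database inflates spurious matches. `groeltyper`
resolves both with three deterministic steps.

**Protein grouping.** After matching each detected peptide (canonicalized:
modification tags stripped, I folded onto L, since Ile/Leu are isobaric and
indistinguishable by MS) against the peptide index, every database protein
receives its set of detected peptides. Proteins with *identical* sets are
observationally equivalent and merge into one protein group. Groups are
sorted by set size, descending; ties are ordered by smallest member
accession, which affects report order only.

**Top Rank Count (TRC) filtering.** For group *G*, TRC(*G*) counts the
detected peptides of *G* that occur in no group with *strictly more*
detected peptides. Equal-size groups do not suppress each other: a peptide
whose largest carriers are two groups of the same size counts for both.
Consequently Σ TRC over groups is ≥ the number of distinct matched peptides,
with equality exactly when every peptide has a unique largest group. A true
positive organism yields one dominant group with many peptides unique to it,
while a false positive's peptides are mostly borrowed from larger groups, so
a threshold on TRC (default ≥ 5, inclusive) removes spurious groups while
keeping low-abundance organisms. The filter is monotone: the survivor set at
threshold *t* + 1 is a subset of that at *t*.

**Modal taxonomy.** Each surviving group is labelled, per rank, with the
most frequent taxon name among its member proteins. Unclassified members do
not vote but remain in the frequency denominator (when at least one member
is classified), so the reported frequency measures agreement across the
whole group; a group whose members are all unclassified is called
`unclassified`. Ties resolve to the lexicographically smaller name and set
an ambiguity flag. Groups are then merged per modal name into taxonomic
groups carrying the union of their detected peptides. This is a modal vote,
not a lowest-common-ancestor assignment.

## Quantification

*Peptide count*: the number of non-redundant detected peptides of the
taxonomic group. A peptide shared between taxa adds one to each — counts are
not split, so the scheme saturates when taxa are close relatives.

*Intensity*: summed MS1 precursor intensities. A peptide with intensity *I*
carried by taxa with peptide totals *n₁…n_k* contributes *I·nⱼ/Σnᵢ* to taxon
*j*; unshared peptides contribute fully. The totals are the count-scheme
quantities (taxon-level, post-merging), and the pass is single — totals are
not recomputed after distribution. Total intensity over taxa equals the
total intensity of assigned peptides exactly.

*PSM*: the intensity sharing rule applied to spectral counts; provided for
comparison.

Relative abundances divide by the grand total; an empty or zero-total
profile yields all zeros with a flag rather than an error.

## Database construction choices

* Protein length filter 6–1500 aa, inclusive; peptide window 6–144 aa with
  ≤ 2 missed cleavages for the index, 6–40 aa when emulating what a search
  engine will actually report.
* Cleavage uses the Keil rule by default (no cut before proline); plain
  `trypsin_p` is selectable because the choice changes peptide sets. No
  N-terminal methionine clipping, no semi-tryptic peptides.
* Protein deduplication is exact-string; I/L folding applies to peptide
  index keys only — isobaric indistinguishability is a property of measured
  peptides, not of protein sequences.
* Proteins containing ambiguous residues (B, J, O, U, X, Z) are digested
  normally; only peptides containing such residues are dropped.
* Registry matching is a case-insensitive, whitespace-trimmed exact match;
  names absent from the registry become `unclassified`. A peptide is
  *standardized* at a rank only if every protein containing it is classified
  there, because specificity cannot be judged against unnamed carriers; it
  is *taxon-specific* if all carriers agree. On any tree-consistent
  taxonomy, taxon-specific counts are therefore non-decreasing from genus to
  phylum.
* The inference TSV holds only taxonomy-bearing records; contaminants go to
  the search FASTA and to a separate peptide exclusion list, mirroring their
  distinct roles (identify vs. discard). Contaminant-matched peptides are
  removed before inference, and contaminant records never enter the peptide
  index.

## The synthetic-data generator

The generator emulates the statistical structure the method relies on, not
raw spectra. One ancestral ~540-aa sequence (the median GroEL length) is
mutated down a tree-consistent taxonomy with per-rank substitution rates
(phylum 0.25 → genus 0.05, within-genus proteins 0.01), so shared-peptide
fraction decays with taxonomic distance — the property that makes GroEL
peptides taxon-specific. Amino-acid draws follow natural bacterial
frequencies (K+R ≈ 11 %), keeping tryptic peptides of 6–40 aa plentiful.

Detection samples each taxon's in-window peptides independently with
probability `detection_prob · (0.3 + 0.7·share/mean_share)`, clipped below
at a floor of 0.02 so rare taxa degrade gradually rather than all-or-nothing.
Intensities are share-scaled log-normals (ln-space μ = 16, σ = 1; e¹⁶ ≈ 9·10⁶
matches typical MS1 precursor magnitudes — the distribution family is the
standard choice for MS1 intensities). Noise consists of decoy tryptic-like
peptides verified absent from the database (5 % of true detections,
emulating search false positives) and contaminant peptides (2 %). The
default community is 12 families with shares ramped 4.8–19.1 before
normalization — a balanced mock-community profile; `skewed` (geometric,
0.2–41.8) and `uniform` profiles are available. All draws derive from one
integer seed.

What the generator does **not** model: spectra and fragmentation, retention
time, peptide-specific detectability/ionization efficiency, charge states,
FDR structure of a real search, isotope labelling, and shared peptides with
organisms outside the database. Passing tests therefore demonstrate the
correctness and robustness of the inference given peptide-level inputs with
realistic sharing structure, not end-to-end accuracy on real spectra.

## Problem sizes and numerics

Tests and the reproduction script use databases of 24 genera × 3 proteins
(~540 aa each, ~4,900 indexed peptides) and communities of 12 families over
five seeds — small enough to run in seconds while exercising every code
path at realistic peptide-sharing densities. Quantile summaries use linear
interpolation (`numpy.percentile` default). Intensity conservation holds to
floating-point round-off; the acceptance report states the observed relative
error. Zero-detection precision is reported as 1.0 with an explicit flag so
threshold sweeps stay plottable. Since no formula for the specificity bars
of a detection sweep is uniquely standard, both the raw false-positive count
and precision are reported.

## Known limitations

* Family-level resolution is the reliable operating point; genus calls are
  exposed but expected to carry false positives at low TRC thresholds.
* Quantification is semiquantitative: protein shares, not cell counts or
  biomass; no correction for detectability or GroEL expression differences.
* The modal vote can misassign a group whose members straddle taxa; the
  reported frequency and ambiguity flag surface, but do not resolve, such
  cases.
* Peptides observed but absent from the database are dropped from inference
  (counted and reported); organisms missing from the database are
  invisible.
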