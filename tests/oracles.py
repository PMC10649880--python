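"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the library's own code paths: digestion is done by
exhaustive enumeration of cleavage-site subsets, and the Top Rank Count by a
double loop over (peptide, group) pairs.
"""

from __future__ import annotations


def oracle_digest(
    sequence: str,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 144,
    keil: bool = True,
    forbidden: str = "BJOUXZ",
) -> set[str]:
    """Exhaustive tryptic digest: split at every cleavage site, then join
    every run of at most ``max_missed + 1`` consecutive fragments."""
    seq = sequence.upper()
    cut_after = []
    for i, ch in enumerate(seq[:-1]):
        if ch in "KR" and not (keil and seq[i + 1] == "P"):
            cut_after.append(i)
    bounds = [0] + [i + 1 for i in cut_after] + [len(seq)]
    fragments = [seq[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]
    peptides: set[str] = set()
    for start in range(len(fragments)):
        for span in range(1, max_missed + 2):
            if start + span > len(fragments):
                break
            pep = "".join(fragments[start : start + span])
            if min_len <= len(pep) <= max_len and not set(pep) & set(forbidden):
                peptides.add(pep)
    return peptides


def oracle_top_rank_counts(peptide_sets: list[frozenset[str]]) -> list[int]:
    """Brute-force TRC: for every group, test each peptide against every
    other group and count it unless a strictly larger group contains it."""
    counts = []
    for g in peptide_sets:
        trc = 0
        for pep in g:
            suppressed = any(
                len(h) > len(g) and pep in h for h in peptide_sets if h is not g
            )
            if not suppressed:
                trc += 1
        counts.append(trc)
    return counts
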