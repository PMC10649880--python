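"""In-silico tryptic digestion and peptide canonicalization.

Digestion is delegated to :func:`pyteomics.parser.cleave` with an explicit
cleavage regex so the rule in force is unambiguous:

* ``trypsin_keil`` — cleave C-terminal of K or R, suppressed when the next
  residue is proline (the classic Keil rule, default).
* ``trypsin_p``   — cleave after every K or R regardless of proline.

Peptide canonicalization folds isoleucine onto leucine because the two
residues are isobaric and indistinguishable by mass spectrometry; the same
function is used for database peptides and detected peptides so that the two
sides of the peptide-matching step always agree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from pyteomics import parser as _pyt_parser

#: Residue codes that are ambiguous or non-standard; peptides containing any
#: of these are dropped from the peptide index (the protein itself is kept).
AMBIGUOUS_RESIDUES = frozenset("BJOUXZ")

_CLEAVAGE_REGEX = {
    "trypsin_keil": r"[KR](?!P)",
    "trypsin_p": r"[KR]",
}

_MOD_GROUPS = re.compile(r"\[[^\]]*\]|\([^)]*\)|\{[^}]*\}")
_NON_UPPER = re.compile(r"[^A-Z]")


@dataclass(frozen=True)
class DigestParams:
    """Parameters of the in-silico tryptic digest.

    Defaults reproduce the database-construction settings: up to two missed
    cleavages, peptide length 6-144 residues, Keil-rule trypsin, and
    exclusion of peptides containing ambiguous residue codes.
    """

    max_missed_cleavages: int = 2
    min_len: int = 6
    max_len: int = 144
    cleavage_rule: str = "trypsin_keil"
    forbid_ambiguous: frozenset[str] = field(default=AMBIGUOUS_RESIDUES)

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("require 1 <= min_len <= max_len")
        if self.cleavage_rule not in _CLEAVAGE_REGEX:
            raise ValueError(f"unknown cleavage rule {self.cleavage_rule!r}")


#: Digest settings used when emulating the detectable-peptide window of an
#: MS search (identification accepts peptides of 6-40 residues).
DETECTION_DIGEST = DigestParams(min_len=6, max_len=40)


def strip_modifications(sequence: str) -> str:
    """Strip modification annotations from a peptide string.

    Removes bracketed/parenthesized mass tags (``C(+57.02)``, ``M[Oxidation]``)
    and any lowercase tags or punctuation, leaving bare uppercase residues.
    """
    bare = _MOD_GROUPS.sub("", sequence)
    return _NON_UPPER.sub("", bare)


def canonicalize_peptide(sequence: str) -> str:
    """Canonical form of a peptide: modifications stripped, upper-case, I->L.

    Isoleucine and leucine are isobaric, so MS identifications cannot tell
    them apart within a peptide; folding I onto L makes equal-mass peptides
    compare equal.  Lowercase characters count as modification tags and are
    stripped, not upper-cased.
    """
    return strip_modifications(sequence).replace("I", "L")


def digest_trypsin(sequence: str, params: DigestParams = DigestParams()) -> set[str]:
    """Tryptic peptides of a protein sequence.

    Returns the set of all maximal cleavage fragments joined across at most
    ``params.max_missed_cleavages`` internal cleavage sites, restricted to
    the configured length window, with peptides containing forbidden
    (ambiguous) residues discarded.  Residues are *not* canonicalized here;
    see :func:`canonicalize_peptide`.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    if not seq.isalpha():
        raise ValueError(f"non-alphabetic character in sequence {sequence!r}")
    peptides = _pyt_parser.cleave(
        seq,
        _CLEAVAGE_REGEX[params.cleavage_rule],
        missed_cleavages=params.max_missed_cleavages,
        regex=True,
    )
    forbidden = params.forbid_ambiguous
    return {
        p
        for p in peptides
        if params.min_len <= len(p) <= params.max_len and not (forbidden & set(p))
    }
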