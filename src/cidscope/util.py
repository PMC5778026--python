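"""Small sequence helpers shared by several modules."""

from __future__ import annotations

import re

from Bio.Seq import Seq

from .errors import TranslationError

DNA_BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}

#: IUPAC nucleotide code -> set of concrete bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement, accepting IUPAC degenerate codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile a degenerate nucleotide pattern into an overlapping-match regex."""
    parts = []
    for code in pattern.upper():
        if code not in IUPAC:
            raise ValueError(f"invalid IUPAC code {code!r} in pattern {pattern!r}")
        bases = IUPAC[code]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def translate_cds(seq: str) -> str:
    """Translate an in-frame nucleotide sequence; internal stops are errors."""
    if len(seq) % 3 != 0:
        raise TranslationError(f"length {len(seq)} is not a multiple of 3")
    aa = str(Seq(seq).translate())
    if "*" in aa:
        raise TranslationError("stop codon inside translated region")
    return aa


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def aa_to_nt_interval(aa_start: int, aa_end: int) -> tuple[int, int]:
    """Map a 1-based inclusive amino-acid interval to the 1-based inclusive
    nucleotide interval in CDS frame: [s, e] -> [3s-2, 3e]."""
    return 3 * aa_start - 2, 3 * aa_end
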