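"""Nucleotide alphabet utilities: reverse complements and IUPAC degenerate codes.

The degenerate alphabet is used throughout the package to write binding-site
consensi such as ``TGASTCA`` (S = C or G) and to scan promoter sequences on
both strands.
"""

from __future__ import annotations

import itertools
import re
from typing import Iterator

DNA = "ACGT"

#: IUPAC nucleotide codes mapped to the set of bases they cover.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Reverse lookup: a set of bases to its single-letter IUPAC code.
CODE_FOR: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)


def revcomp(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) nucleotide string."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def is_exact_dna(seq: str) -> bool:
    """True if *seq* is a non-empty string over {A,C,G,T} (case-insensitive)."""
    s = seq.upper()
    return len(s) > 0 and all(c in DNA for c in s)


def validate_pattern(pattern: str) -> str:
    """Uppercase *pattern* and check every letter is an IUPAC code."""
    p = pattern.upper()
    bad = [c for c in p if c not in IUPAC_CODES]
    if bad:
        raise ValueError(f"invalid IUPAC letters {bad!r} in pattern {pattern!r}")
    return p


def expand(pattern: str) -> tuple[str, ...]:
    """All exact DNA strings covered by a degenerate *pattern* (sorted)."""
    p = validate_pattern(pattern)
    pools = [sorted(IUPAC_CODES[c]) for c in p]
    return tuple("".join(t) for t in itertools.product(*pools))


def compile_pattern(pattern: str) -> re.Pattern[str]:
    """Regex matching *pattern*, one character class per degenerate position."""
    p = validate_pattern(pattern)
    parts = []
    for c in p:
        bases = IUPAC_CODES[c]
        parts.append(c if len(bases) == 1 else "[" + "".join(sorted(bases)) + "]")
    return re.compile("".join(parts))


def iter_matches(sequence: str, pattern: str) -> Iterator[int]:
    """Yield 0-based start indices of every (overlapping) match of *pattern*."""
    rx = compile_pattern(pattern)
    # lookahead so overlapping occurrences are all reported
    overlap = re.compile("(?=" + rx.pattern + ")")
    seq = sequence.upper()
    for m in overlap.finditer(seq):
        yield m.start()


def contains(sequence: str, pattern: str, both_strands: bool = True) -> bool:
    """True if *pattern* occurs in *sequence* (optionally on either strand)."""
    seq = sequence.upper()
    rx = compile_pattern(pattern)
    if rx.search(seq):
        return True
    if both_strands and rx.search(revcomp(seq)):
        return True
    return False


def matches_pattern(seq: str, pattern: str) -> bool:
    """True if *seq* as a whole is one of the strings covered by *pattern*."""
    p = validate_pattern(pattern)
    s = seq.upper()
    return len(s) == len(p) and all(c in IUPAC_CODES[q] for c, q in zip(s, p))


def code_for(bases: set[str] | frozenset[str]) -> str:
    """IUPAC letter covering exactly *bases* (must be a non-empty subset of ACGT)."""
    key = frozenset(b.upper() for b in bases)
    if key not in CODE_FOR:
        raise ValueError(f"no IUPAC code for base set {sorted(bases)!r}")
    return CODE_FOR[key]
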