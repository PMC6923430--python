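"""Small sequence utilities shared across modules."""

from __future__ import annotations

import re

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC degenerate pattern into a regex (no N wildcard for gaps)."""
    parts = []
    for ch in pattern.upper():
        try:
            opts = IUPAC[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def matches_iupac(seq: str, pattern: str) -> bool:
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC.get(p, "") for b, p in zip(seq.upper(), pattern.upper()))


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def max_homopolymer_run(seq: str, base: str) -> int:
    """Length of the longest run of `base` in `seq`."""
    best = run = 0
    for ch in seq.upper():
        run = run + 1 if ch == base else 0
        best = max(best, run)
    return best


def homopolymer_runs(seq: str, min_len: int = 3) -> int:
    """Number of maximal homopolymer runs of length >= min_len."""
    count = 0
    s = seq.upper()
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        if j - i >= min_len:
            count += 1
        i = j
    return count
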