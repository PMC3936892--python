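"""Small sequence utilities shared across the package.

All sequences are handled internally as uppercase DNA (T, not U); RNA
input is normalized on entry.  Coordinates are 0-based half-open
internally and converted to 1-based only in human-readable reports.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Watson-Crick plus G:U wobble, on the DNA alphabet (U stored as T).
CANONICAL_PAIRS = frozenset(
    {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
)

VALID_BASES = frozenset("ACGTN")


def normalize(seq: str) -> str:
    """Uppercase a sequence and convert RNA (U) to the DNA alphabet."""
    return seq.upper().replace("U", "T")


def is_valid_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= VALID_BASES


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """G+C content of ``seq`` as a percentage of its length."""
    if not seq:
        raise ValueError("GC content of an empty sequence is undefined")
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / len(seq)


def can_pair(a: str, b: str) -> bool:
    """True if two bases can form a canonical (WC or G:U) pair; N never pairs."""
    return (a, b) in CANONICAL_PAIRS


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length sequences.

    Unequal lengths are an error: the conserved-miRNA mismatch bound
    tolerates no indels.
    """
    if len(a) != len(b):
        raise ValueError(f"hamming() requires equal lengths ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))
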