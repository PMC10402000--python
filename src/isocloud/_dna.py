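"""Low-level DNA string helpers shared across modules."""

import re

_RC_TABLE = str.maketrans("ACGT", "TGCA")
_NON_ACGT = re.compile("[^ACGT]+")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_RC_TABLE)[::-1]


def canonical_kmer(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def split_at_ambiguous(read: str):
    """Split an uppercased read into N-free fragments.

    Reads containing ambiguous bases are split rather than discarded so
    that low-coverage clouds do not lose whole reads to a single N call.
    """
    return [f for f in _NON_ACGT.split(read.upper()) if f]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))
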