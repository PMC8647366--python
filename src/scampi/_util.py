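"""Small shared helpers."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence over {A,C,G,T,N} (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def strip_gem_suffix(barcode: str) -> str:
    """Drop a trailing 10x gem-group suffix such as ``-1`` if present."""
    if "-" in barcode:
        return barcode.split("-", 1)[0]
    return barcode
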