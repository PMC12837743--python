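"""Small shared helpers."""

from __future__ import annotations

import zlib

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming_prefix(seq: str, prefix: str) -> int:
    """Mismatch count between ``prefix`` and the start of ``seq``.

    Returns ``len(prefix)`` (worst case) when ``seq`` is shorter than the
    prefix, so callers can compare against a mismatch budget directly.
    """
    if len(seq) < len(prefix):
        return len(prefix)
    return sum(a != b for a, b in zip(prefix, seq))


def stable_label_seed(label: str) -> int:
    # crc32 keeps the derived stream seed in [0, 2^31) and reproducible
    # across interpreter runs (unlike hash()).
    return zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF
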