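"""Pyrimidine-collapsed sequence-context and substitution-channel encodings.

Substitutions are represented with the mutated base read as a pyrimidine
(C or T); a purine-reference substitution is mapped onto the reverse
complement strand.  With one flanking base on each side (k=1) this yields
the standard 96 trinucleotide channels (6 substitution types x 16
contexts); with two flanking bases (k=2), 1536 pentanucleotide channels.

Everything downstream (spectra, abundances, expected-mutation models)
works with the integer context indices defined here.  Context index
arrays over a chromosome are computed vectorised and cached on the
genome object.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: the six pyrimidine-stated substitution types, in canonical order
SUBSTITUTION_TYPES = (
    ("C", "A"), ("C", "G"), ("C", "T"),
    ("T", "A"), ("T", "C"), ("T", "G"),
)

# byte-value -> base code lookup (N and anything unexpected -> 4)
_ASCII_CODE = np.full(256, 4, dtype=np.int8)
for _b, _i in _BASE_CODE.items():
    _ASCII_CODE[ord(_b)] = _i
    _ASCII_CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def n_contexts(k: int) -> int:
    """Number of pyrimidine-centred contexts of width 2k+1 (32 or 512)."""
    return 2 * 4 ** (2 * k)


def n_channels(k: int) -> int:
    """Number of substitution channels of width 2k+1 (96 or 1536)."""
    return 3 * n_contexts(k)


@lru_cache(maxsize=None)
def canonical_contexts(k: int) -> tuple[str, ...]:
    """All pyrimidine-centred contexts of width 2k+1, lexicographic order."""
    w = 2 * k + 1
    out = []
    for letters in product(BASES, repeat=w):
        if letters[k] in "CT":
            out.append("".join(letters))
    return tuple(sorted(out))


@lru_cache(maxsize=None)
def context_index(k: int) -> dict[str, int]:
    return {c: i for i, c in enumerate(canonical_contexts(k))}


@lru_cache(maxsize=None)
def channel_labels(k: int) -> tuple[str, ...]:
    """Channel labels like ``A[C>T]G``, ordered by (substitution, context)."""
    labels = []
    for ref, alt in SUBSTITUTION_TYPES:
        for ctx in canonical_contexts(k):
            if ctx[k] == ref:
                labels.append(f"{ctx[:k]}[{ref}>{alt}]{ctx[k + 1:]}")
    return tuple(labels)


@lru_cache(maxsize=None)
def channel_index(k: int) -> dict[str, int]:
    return {c: i for i, c in enumerate(channel_labels(k))}


def channel_label(ref: str, alt: str, context: str) -> str:
    k = len(context) // 2
    return f"{context[:k]}[{ref}>{alt}]{context[k + 1:]}"


@lru_cache(maxsize=None)
def _collapse_lut(k: int) -> np.ndarray:
    """Map a raw 4^(2k+1) window code onto its canonical context index.

    Purine-centred windows are reverse complemented first, so plus and
    minus strand readings of the same duplex position share one index.
    """
    w = 2 * k + 1
    cidx = context_index(k)
    lut = np.empty(4 ** w, dtype=np.int16)
    for code, letters in enumerate(product(BASES, repeat=w)):
        s = "".join(letters)
        if s[k] not in "CT":
            s = revcomp(s)
        lut[code] = cidx[s]
    return lut


@lru_cache(maxsize=None)
def _channel_lut(k: int) -> np.ndarray:
    """(context index, pyrimidine-strand alt code) -> channel index; -1 invalid."""
    lut = np.full((n_contexts(k), 4), -1, dtype=np.int16)
    chan = channel_index(k)
    for ctx, ci in context_index(k).items():
        ref = ctx[k]
        for alt in BASES:
            if alt == ref:
                continue
            lut[ci, _BASE_CODE[alt]] = chan[channel_label(ref, alt, ctx)]
    return lut


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else -> 4, as an int8 array."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ASCII_CODE[raw]


def context_index_array(seq: str, k: int) -> np.ndarray:
    """Per-position canonical context index; -1 at edges and N windows.

    Position ``i`` (0-based) gets the pyrimidine-collapsed index of the
    window ``seq[i-k : i+k+1]`` when that window lies inside the sequence
    and contains no N.
    """
    w = 2 * k + 1
    codes = encode_sequence(seq).astype(np.int64)
    L = len(codes)
    out = np.full(L, -1, dtype=np.int16)
    if L < w:
        return out
    m = L - w + 1
    window = np.zeros(m, dtype=np.int64)
    bad = np.zeros(m, dtype=bool)
    for j in range(w):
        col = codes[j : j + m]
        window = window * 4 + np.where(col == 4, 0, col)
        bad |= col == 4
    vals = _collapse_lut(k)[window]
    vals[bad] = -1
    out[k : k + m] = vals
    return out


def channel_of(ref: str, alt: str, context: str) -> tuple[str, str, str]:
    """Collapse a substitution onto its pyrimidine-stated channel.

    Returns ``(ref_pyrimidine, alt, context)`` with the context centred on
    the pyrimidine.  ``context`` must be odd-length with ``ref`` at its
    centre.
    """
    k = len(context) // 2
    if len(context) != 2 * k + 1 or context[k] != ref:
        raise ValueError(f"context {context!r} is not centred on ref {ref!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    if ref in "CT":
        return ref, alt, context
    return COMPLEMENT[ref], COMPLEMENT[alt], revcomp(context)


def channel_codes_for(ctx_idx: np.ndarray, alt_pyr_codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorised (context index, pyrimidine alt code) -> channel index."""
    return _channel_lut(k)[ctx_idx, alt_pyr_codes]
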