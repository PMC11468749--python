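"""Adaptive order-k context-model arithmetic coder over the DNA alphabet.

Implements a classic 32-bit binary arithmetic coder (carry handling via
underflow-bit counting) driven by an adaptive context model: the coding
distribution for the next base is derived from Laplace-smoothed counts of
the bases previously seen after the same ``order``-base context.  Counts
for a context are halved whenever their smoothed total exceeds 2**16,
which bounds adaptation lag and keeps cumulative frequencies inside the
coder's precision.

Two model variants share this machinery:

* plain — counts are indexed by the literal (order+1)-mer context+base;
* reverse-complement canonical — counts are indexed by the lexicographic
  minimum of the (order+1)-mer and its reverse complement, so a DNA word
  and its opposite-strand form accumulate (and draw on) the same
  statistics.  This is the mechanism by which DNA-aware compressors
  exploit inverted repeats.

Both variants are fully deterministic and exactly invertible: the decoder
replays the identical model updates.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

_FULL = 0xFFFFFFFF
_HALF = 0x80000000
_QTR = 0x40000000
_QTR3 = 0xC0000000
_CAP = 1 << 16  # halve context counts beyond this smoothed total


@lru_cache(maxsize=8)
def canonical_word_table(word_length: int) -> tuple:
    """Map every base-4 encoded word of ``word_length`` letters to the code
    of the lexicographic minimum of itself and its reverse complement."""
    ids = np.arange(4**word_length, dtype=np.int64)
    rc = np.zeros_like(ids)
    tmp = ids.copy()
    for _ in range(word_length):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return tuple(np.minimum(ids, rc).tolist())


def encode_codes(codes, order: int, smoothing: int, rc_canonical: bool) -> bytes:
    """Arithmetic-code a sequence of base codes (ints 0..3); returns the
    packed code bytes (no header)."""
    canon = canonical_word_table(order + 1) if rc_canonical else None
    counts = [0] * (4 ** (order + 1))
    mask = (1 << (2 * order)) - 1
    low, high, pending = 0, _FULL, 0
    bits: list[int] = []
    ap = bits.append
    ext = bits.extend
    ctx = 0
    sm = smoothing
    for s in codes:
        b = ctx << 2
        if canon is None:
            i0, i1, i2, i3 = b, b + 1, b + 2, b + 3
        else:
            i0, i1, i2, i3 = canon[b], canon[b + 1], canon[b + 2], canon[b + 3]
        f0 = counts[i0] + sm
        f1 = counts[i1] + sm
        f2 = counts[i2] + sm
        f3 = counts[i3] + sm
        tot = f0 + f1 + f2 + f3
        if tot > _CAP:
            counts[i0] >>= 1
            counts[i1] >>= 1
            counts[i2] >>= 1
            counts[i3] >>= 1
            f0 = counts[i0] + sm
            f1 = counts[i1] + sm
            f2 = counts[i2] + sm
            f3 = counts[i3] + sm
            tot = f0 + f1 + f2 + f3
        if s == 0:
            clo, chi, idx = 0, f0, i0
        elif s == 1:
            clo, chi, idx = f0, f0 + f1, i1
        elif s == 2:
            clo, chi, idx = f0 + f1, f0 + f1 + f2, i2
        else:
            clo, chi, idx = tot - f3, tot, i3
        span = high - low + 1
        high = low + (span * chi) // tot - 1
        low = low + (span * clo) // tot
        while True:
            if high < _HALF:
                ap(0)
                if pending:
                    ext([1] * pending)
                    pending = 0
            elif low >= _HALF:
                ap(1)
                if pending:
                    ext([0] * pending)
                    pending = 0
                low -= _HALF
                high -= _HALF
            elif low >= _QTR and high < _QTR3:
                pending += 1
                low -= _QTR
                high -= _QTR
            else:
                break
            low <<= 1
            high = (high << 1) | 1
        counts[idx] += 1
        ctx = (b | s) & mask
    pending += 1
    if low < _QTR:
        ap(0)
        ext([1] * pending)
    else:
        ap(1)
        ext([0] * pending)
    return np.packbits(np.array(bits, dtype=np.uint8)).tobytes()


def decode_codes(
    payload: bytes, n_symbols: int, order: int, smoothing: int, rc_canonical: bool
) -> list[int]:
    """Invert :func:`encode_codes`; returns the list of base codes."""
    canon = canonical_word_table(order + 1) if rc_canonical else None
    counts = [0] * (4 ** (order + 1))
    mask = (1 << (2 * order)) - 1
    bits = np.unpackbits(np.frombuffer(payload, dtype=np.uint8)).tolist()
    bits.extend([0] * 64)  # decoder may read past the flushed tail
    pos = 32
    value = 0
    for bit in bits[:32]:
        value = (value << 1) | bit
    low, high = 0, _FULL
    out: list[int] = []
    ap = out.append
    ctx = 0
    sm = smoothing
    for _ in range(n_symbols):
        b = ctx << 2
        if canon is None:
            i0, i1, i2, i3 = b, b + 1, b + 2, b + 3
        else:
            i0, i1, i2, i3 = canon[b], canon[b + 1], canon[b + 2], canon[b + 3]
        f0 = counts[i0] + sm
        f1 = counts[i1] + sm
        f2 = counts[i2] + sm
        f3 = counts[i3] + sm
        tot = f0 + f1 + f2 + f3
        if tot > _CAP:
            counts[i0] >>= 1
            counts[i1] >>= 1
            counts[i2] >>= 1
            counts[i3] >>= 1
            f0 = counts[i0] + sm
            f1 = counts[i1] + sm
            f2 = counts[i2] + sm
            f3 = counts[i3] + sm
            tot = f0 + f1 + f2 + f3
        span = high - low + 1
        scaled = ((value - low + 1) * tot - 1) // span
        if scaled < f0:
            s, clo, chi, idx = 0, 0, f0, i0
        elif scaled < f0 + f1:
            s, clo, chi, idx = 1, f0, f0 + f1, i1
        elif scaled < f0 + f1 + f2:
            s, clo, chi, idx = 2, f0 + f1, f0 + f1 + f2, i2
        else:
            s, clo, chi, idx = 3, tot - f3, tot, i3
        high = low + (span * chi) // tot - 1
        low = low + (span * clo) // tot
        while True:
            if high < _HALF:
                pass
            elif low >= _HALF:
                low -= _HALF
                high -= _HALF
                value -= _HALF
            elif low >= _QTR and high < _QTR3:
                low -= _QTR
                high -= _QTR
                value -= _QTR
            else:
                break
            low <<= 1
            high = (high << 1) | 1
            value = (value << 1) | bits[pos]
            pos += 1
        ap(s)
        counts[idx] += 1
        ctx = (b | s) & mask
    return out
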