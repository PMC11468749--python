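"""Genome composition statistics: nucleotide frequencies, AT content,
k-mer frequency tables, and oligonucleotide usage variance (OUV).

OUV measures how far genome-wide k-mer (default tetranucleotide, k=4)
frequencies deviate from what base composition alone predicts:

    OUV = 1/(N-1) * sum over all N = 4^k words w of
          (f(w) - prod over letters x of w of f(x))**2

A genome whose words occur exactly as often as the product of their
single-nucleotide frequencies (an i.i.d. genome) has OUV near zero;
selective word usage inflates OUV.  Counting is single-strand, linear,
with overlapping windows stepped by one; windows containing any non-ACGT
letter are skipped, and ambiguity letters are excluded from single-base
frequencies as well.  A flag enables circular (wraparound) counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NucleotideFrequencies",
    "KmerFrequencyTable",
    "OuvResult",
    "nucleotide_frequencies",
    "at_content",
    "kmer_frequencies",
    "expected_word_frequency",
    "ouv",
]

_ALPHABET = "ACGT"

# byte value -> 0..3 for ACGT (upper/lower case), 255 otherwise
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


class CompositionError(ValueError):
    """Raised when a sequence cannot yield the requested statistic."""


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a sequence string to uint8 codes (A=0, C=1, G=2, T=3, other=255)."""
    if not sequence:
        raise CompositionError("empty sequence")
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    return _CODE[raw]


@dataclass(frozen=True)
class NucleotideFrequencies:
    """Single-nucleotide frequencies over unambiguous (A/C/G/T) positions."""

    f_A: float
    f_C: float
    f_G: float
    f_T: float
    n_valid_bases: int

    def as_array(self) -> np.ndarray:
        return np.array([self.f_A, self.f_C, self.f_G, self.f_T])

    def __getitem__(self, base: str) -> float:
        try:
            return self.as_array()[_ALPHABET.index(base)]
        except ValueError:
            raise CompositionError(f"invalid base {base!r}") from None


@dataclass(frozen=True)
class KmerFrequencyTable:
    """Frequencies of all 4**k words over valid (fully unambiguous) windows.

    ``frequencies`` is a dense length-4**k array indexed by the base-4 code
    of the word (A=0, C=1, G=2, T=3, most significant letter first); words
    never observed hold zero.
    """

    k: int
    frequencies: np.ndarray = field(repr=False)
    n_valid_windows: int

    def frequency(self, word: str) -> float:
        return float(self.frequencies[_word_index(word)])

    def as_dict(self) -> dict[str, float]:
        return {
            _index_word(i, self.k): float(f) for i, f in enumerate(self.frequencies)
        }


@dataclass(frozen=True)
class OuvResult:
    ouv: float
    k: int
    n_words: int


def _word_index(word: str) -> int:
    idx = 0
    for ch in word:
        c = _ALPHABET.find(ch)
        if c < 0:
            raise CompositionError(f"invalid letter {ch!r} in word {word!r}")
        idx = idx * 4 + c
    return idx


def _index_word(idx: int, k: int) -> str:
    letters = []
    for _ in range(k):
        letters.append(_ALPHABET[idx & 3])
        idx >>= 2
    return "".join(reversed(letters))


def nucleotide_frequencies(sequence: str) -> NucleotideFrequencies:
    """Frequencies of A, C, G, T among unambiguous positions.

    Ambiguity letters (N, R, Y, ...) are excluded from both numerator and
    denominator.  Raises if no A/C/G/T base is present.
    """
    codes = encode_sequence(sequence)
    counts = np.bincount(codes[codes < 4], minlength=4)
    n = int(counts.sum())
    if n == 0:
        raise CompositionError("sequence contains no A/C/G/T base")
    f = counts / n
    return NucleotideFrequencies(float(f[0]), float(f[1]), float(f[2]), float(f[3]), n)


def at_content(freqs: NucleotideFrequencies | str) -> float:
    """AT content: (A+T) / (A+C+G+T), ambiguity letters excluded."""
    if isinstance(freqs, str):
        freqs = nucleotide_frequencies(freqs)
    return freqs.f_A + freqs.f_T


def kmer_frequencies(sequence: str, k: int = 4, circular: bool = False) -> KmerFrequencyTable:
    """Overlapping k-mer frequencies on a single strand.

    Windows are stepped by one base; a window containing any non-ACGT
    letter is skipped entirely.  With ``circular=True`` the k-1 wraparound
    windows are counted as well.
    """
    if k < 1:
        raise CompositionError("k must be >= 1")
    codes = encode_sequence(sequence)
    if circular and len(codes) >= k:
        codes = np.concatenate([codes, codes[: k - 1]])
    if len(codes) < k:
        raise CompositionError(f"sequence shorter than k={k}")
    # rolling base-4 word codes; invalid windows masked out
    valid = codes < 4
    window_valid = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    n_valid = int(window_valid.sum())
    if n_valid == 0:
        raise CompositionError("no window free of ambiguity letters")
    windows = np.lib.stride_tricks.sliding_window_view(
        np.where(valid, codes, 0).astype(np.int64), k
    )
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    word_codes = windows[window_valid] @ powers
    counts = np.bincount(word_codes, minlength=4**k)
    return KmerFrequencyTable(k=k, frequencies=counts / n_valid, n_valid_windows=n_valid)


def expected_word_frequency(word: str, freqs: NucleotideFrequencies) -> float:
    """Expected word frequency under base composition alone: the product of
    the word's single-letter frequencies, e.g. f(A)f(G)f(C)f(T) for AGCT."""
    p = 1.0
    arr = freqs.as_array()
    for ch in word:
        c = _ALPHABET.find(ch)
        if c < 0:
            raise CompositionError(f"invalid letter {ch!r} in word {word!r}")
        p *= arr[c]
    return p


def ouv(sequence: str, k: int = 4, circular: bool = False) -> OuvResult:
    """Oligonucleotide usage variance over all 4**k words.

    Average squared difference between observed word frequencies and the
    products of their single-nucleotide frequencies, normalized by N-1
    (N = 4**k), sample-variance style.
    """
    table = kmer_frequencies(sequence, k=k, circular=circular)
    base = nucleotide_frequencies(sequence).as_array()
    n_words = 4**k
    # expected freq of every word as outer product of per-position letter freqs
    expected = np.ones(1)
    for _ in range(k):
        expected = np.kron(expected, base)
    diff = table.frequencies - expected
    value = float(diff @ diff) / (n_words - 1)
    return OuvResult(ouv=value, k=k, n_words=n_words)
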