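"""Genome compressibility measurement with pluggable backends.

The compression ratio of a genome — sequence length in bases divided by
compressed size in bytes — is a practical proxy for its redundancy: an
incompressible (ratio near the 2-bits-per-base floor of ~4) genome is
close to random, a highly compressible one is pattern-rich.

Built-in backends:

* ``deflate`` / ``bzip2`` / ``lzma`` — standard general-purpose codecs
  applied to the raw base stream;
* ``ctx`` — an adaptive order-k context-model arithmetic coder over the
  literal strand (the general-purpose, ZPAQ-role backend);
* ``ctx-rc`` — the same coder with reverse-complement-canonical word
  statistics, so a pattern and its opposite-strand form share a model
  (the DNA-aware, MBGC-role backend).  The single design difference from
  ``ctx`` isolates the value of strand symmetry for compression.

External ``zpaq``/``mbgc`` binaries can additionally be registered as
optional adapters; nothing in the package requires them.
"""

from __future__ import annotations

import bz2
import lzma
import os
import shutil
import subprocess
import tempfile
import zlib
from dataclasses import dataclass
from pathlib import Path

from grc import _rangecoder

__all__ = [
    "CompressionResult",
    "ContextModelConfig",
    "BackendError",
    "list_backends",
    "sequence_to_stream",
    "compress_ratio",
    "context_encode",
    "context_decode",
    "reverse_complement",
    "rc_canonical_key",
    "register_external_backend",
    "unregister_external_backend",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T bytes
_CODE_BASE = b"ACGT"

_MAGIC_ORDER_MAX = 12


class BackendError(RuntimeError):
    pass


@dataclass(frozen=True)
class ContextModelConfig:
    """Configuration of the context-model coder.

    order
        context length in bases (0–12); 4**(order+1) word counters.
    rc_canonical
        use reverse-complement-canonical word statistics.
    smoothing_count
        Laplace pseudo-count added to every base in every context
        (positive integer; the coder works on integer frequencies).
    precision_bits
        arithmetic-coder register width; 32 is the implemented width and
        the only supported value.
    """

    order: int = 8
    rc_canonical: bool = False
    smoothing_count: int = 1
    precision_bits: int = 32

    def __post_init__(self):
        if not 0 <= self.order <= _MAGIC_ORDER_MAX:
            raise ValueError(f"order must be in [0, {_MAGIC_ORDER_MAX}]")
        if not (isinstance(self.smoothing_count, int) and self.smoothing_count > 0):
            raise ValueError("smoothing_count must be a positive integer")
        if self.precision_bits != 32:
            raise ValueError("only 32-bit coder precision is implemented")


@dataclass(frozen=True)
class CompressionResult:
    backend: str
    input_bases: int
    compressed_bytes: int

    def __post_init__(self):
        if self.compressed_bytes <= 0:
            raise ValueError("compressed_bytes must be positive")

    @property
    def ratio(self) -> float:
        """input bases / compressed bytes; > 4 means beating 2 bits/base."""
        return self.input_bases / self.compressed_bytes

    @property
    def bits_per_base(self) -> float:
        return 8.0 * self.compressed_bytes / self.input_bases


def sequence_to_stream(sequence: str) -> bytes:
    """Normalize a sequence to a one-byte-per-base upper-case stream.

    Whitespace (FASTA line breaks) is stripped; ambiguity letters are kept
    verbatim.  The stream length equals the genome length in bases.
    """
    stream = "".join(sequence.split()).upper().encode("ascii")
    if not stream:
        raise ValueError("empty sequence")
    return stream


def reverse_complement(word: str) -> str:
    return word.translate(_COMPLEMENT)[::-1]


def rc_canonical_key(word: str) -> str:
    """Lexicographic minimum of a word and its reverse complement."""
    for ch in word:
        if ch not in "ACGT":
            raise ValueError(f"invalid letter {ch!r}")
    rc = reverse_complement(word)
    return min(word, rc)


# --- context-coder container ------------------------------------------------
#
# Layout:
#   8-byte header: order (1), flags (1: bit0 rc_canonical, bit1 exceptions),
#                  smoothing (1), stream length (5, big-endian)
#   optional exception block (when flags bit1): 4-byte big-endian length,
#       then zlib(varint position deltas interleaved with literal bytes)
#       covering every non-ACGT stream position
#   arithmetic-coded payload over the A/C/G/T symbols only


def _write_varint(out: bytearray, v: int) -> None:
    while v >= 0x80:
        out.append((v & 0x7F) | 0x80)
        v >>= 7
    out.append(v)


def _read_varint(buf: bytes, pos: int) -> tuple[int, int]:
    v = 0
    shift = 0
    while True:
        b = buf[pos]
        pos += 1
        v |= (b & 0x7F) << shift
        if b < 0x80:
            return v, pos
        shift += 7


def context_encode(stream: bytes, config: ContextModelConfig | None = None) -> bytes:
    """Compress a base stream with the adaptive context-model coder."""
    if config is None:
        config = ContextModelConfig()
    if not stream:
        raise ValueError("empty stream")
    n = len(stream)
    codes = []
    exceptions: list[tuple[int, int]] = []
    get = _BASE_CODE.get
    for i, byte in enumerate(stream):
        c = get(byte)
        if c is None:
            exceptions.append((i, byte))
        else:
            codes.append(c)
    flags = (1 if config.rc_canonical else 0) | (2 if exceptions else 0)
    header = bytes(
        [config.order, flags, config.smoothing_count]
    ) + n.to_bytes(5, "big")
    parts = [header]
    if exceptions:
        raw = bytearray()
        prev = -1
        for pos_i, byte in exceptions:
            _write_varint(raw, pos_i - prev - 1)
            raw.append(byte)
            prev = pos_i
        block = zlib.compress(bytes(raw), 9)
        parts.append(len(block).to_bytes(4, "big"))
        parts.append(block)
    if codes:
        parts.append(
            _rangecoder.encode_codes(
                codes, config.order, config.smoothing_count, config.rc_canonical
            )
        )
    return b"".join(parts)


def context_decode(blob: bytes) -> bytes:
    """Invert :func:`context_encode`, recovering the exact base stream."""
    if len(blob) < 8:
        raise ValueError("truncated container: missing header")
    order, flags = blob[0], blob[1]
    smoothing = blob[2]
    n = int.from_bytes(blob[3:8], "big")
    rc_canonical = bool(flags & 1)
    pos = 8
    exceptions: list[tuple[int, int]] = []
    if flags & 2:
        block_len = int.from_bytes(blob[pos : pos + 4], "big")
        pos += 4
        raw = zlib.decompress(blob[pos : pos + block_len])
        pos += block_len
        p = 0
        at = -1
        while p < len(raw):
            delta, p = _read_varint(raw, p)
            at += delta + 1
            exceptions.append((at, raw[p]))
            p += 1
    n_codes = n - len(exceptions)
    codes = (
        _rangecoder.decode_codes(blob[pos:], n_codes, order, smoothing, rc_canonical)
        if n_codes
        else []
    )
    out = bytearray()
    exc_iter = iter(exceptions)
    nxt = next(exc_iter, None)
    ci = 0
    for i in range(n):
        if nxt is not None and nxt[0] == i:
            out.append(nxt[1])
            nxt = next(exc_iter, None)
        else:
            out.append(_CODE_BASE[codes[ci]])
            ci += 1
    return bytes(out)


# --- backend registry -------------------------------------------------------

_BUILTIN = ("deflate", "bzip2", "lzma", "ctx", "ctx-rc")
_EXTERNAL: dict[str, Path] = {}

# command templates for the optional external tools; {in}/{out} are replaced
_EXTERNAL_COMMANDS = {
    "zpaq": ["{bin}", "-n", "-o", "{out}", "--zpaq", "{in}"],  # lrzip --zpaq
    "mbgc": ["{bin}", "c", "-i", "{in}", "{out}"],
}


def register_external_backend(tool: str, binary_path: str | Path) -> None:
    """Register an external compressor binary (``zpaq`` via lrzip, or
    ``mbgc``) as an optional backend.  Never required by the package."""
    if tool not in _EXTERNAL_COMMANDS:
        raise BackendError(f"unknown external tool {tool!r}")
    binary_path = Path(binary_path)
    if not binary_path.exists() or not os.access(binary_path, os.X_OK):
        raise BackendError(f"{tool}: binary {binary_path} not found or not executable")
    _EXTERNAL[tool] = binary_path


def unregister_external_backend(tool: str) -> None:
    _EXTERNAL.pop(tool, None)


def list_backends() -> list[str]:
    return list(_BUILTIN) + sorted(_EXTERNAL)


def _external_compressed_size(tool: str, stream: bytes) -> int:
    binary = _EXTERNAL[tool]
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "genome.fa"
        outfile = Path(tmp) / "genome.cmp"
        infile.write_bytes(b">genome\n" + stream + b"\n")
        cmd = [
            part.replace("{bin}", str(binary))
            .replace("{in}", str(infile))
            .replace("{out}", str(outfile))
            for part in _EXTERNAL_COMMANDS[tool]
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0 or not outfile.exists():
            raise BackendError(
                f"{tool} failed (exit {proc.returncode}): {proc.stderr.strip()}"
            )
        return outfile.stat().st_size


def compress_ratio(
    sequence: str | bytes,
    backend: str = "ctx",
    config: ContextModelConfig | None = None,
) -> CompressionResult:
    """Compress a genome sequence and report its compression ratio.

    ``sequence`` may be a string (whitespace stripped, upper-cased) or an
    already-normalized byte stream.  The ratio's numerator is the base
    count of the stream, never file-format overhead.
    """
    stream = sequence_to_stream(sequence) if isinstance(sequence, str) else sequence
    if not stream:
        raise ValueError("empty sequence")
    if backend == "deflate":
        size = len(zlib.compress(stream, 9))
    elif backend == "bzip2":
        size = len(bz2.compress(stream, 9))
    elif backend == "lzma":
        size = len(lzma.compress(stream, preset=6))
    elif backend == "ctx":
        cfg = config or ContextModelConfig()
        if cfg.rc_canonical:
            raise ValueError("backend 'ctx' requires rc_canonical=False")
        size = len(context_encode(stream, cfg))
    elif backend == "ctx-rc":
        cfg = config or ContextModelConfig(rc_canonical=True)
        if not cfg.rc_canonical:
            raise ValueError("backend 'ctx-rc' requires rc_canonical=True")
        size = len(context_encode(stream, cfg))
    elif backend in _EXTERNAL:
        size = _external_compressed_size(backend, stream)
    else:
        raise BackendError(f"unknown or unavailable backend {backend!r}")
    return CompressionResult(
        backend=backend, input_bases=len(stream), compressed_bytes=size
    )
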