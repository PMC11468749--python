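"""Context-coder correctness and the reverse-complement mechanism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grc.compression import (
    BackendError,
    CompressionResult,
    ContextModelConfig,
    compress_ratio,
    context_decode,
    context_encode,
    list_backends,
    rc_canonical_key,
    register_external_backend,
    reverse_complement,
    sequence_to_stream,
)
from grc.synthetic import GenomeSpec, generate_genome


class TestStream:
    def test_strips_whitespace_and_uppercases(self):
        assert sequence_to_stream("acgt\nACGT") == b"ACGTACGT"

    def test_length_equals_bases(self):
        seq = "ACGTN" * 7
        assert len(sequence_to_stream(seq)) == len(seq)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            sequence_to_stream(" \n ")


class TestCanonicalKey:
    def test_palindrome_maps_to_itself(self):
        assert rc_canonical_key("ACGT") == "ACGT"

    def test_homopolymer(self):
        assert rc_canonical_key("TTTT") == "AAAA"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=12))
    def test_strand_symmetry(self, word):
        assert rc_canonical_key(word) == rc_canonical_key(reverse_complement(word))
        assert rc_canonical_key(word) <= word

    def test_invalid_letter(self):
        with pytest.raises(ValueError):
            rc_canonical_key("ACGN")


class TestRoundTrip:
    @pytest.mark.parametrize("order", [0, 2, 8])
    @pytest.mark.parametrize("rc", [False, True])
    def test_fuzzed_sequences(self, order, rc, rng):
        cfg = ContextModelConfig(order=order, rc_canonical=rc)
        for i in range(12):
            n = int(rng.integers(1, 3000))
            alphabet = list("ACGTNRY") if i % 3 == 0 else list("ACGT")
            stream = "".join(rng.choice(alphabet, size=n)).encode()
            assert context_decode(context_encode(stream, cfg)) == stream

    def test_all_ambiguous_stream(self):
        stream = b"NNNNNNNN"
        assert context_decode(context_encode(stream)) == stream

    def test_truncated_container_rejected(self):
        with pytest.raises(ValueError):
            context_decode(b"\x08\x00")

    def test_header_records_order_and_length(self):
        blob = context_encode(b"ACGTACGT", ContextModelConfig(order=5))
        assert blob[0] == 5
        assert int.from_bytes(blob[3:8], "big") == 8


class TestBackends:
    def test_builtins_present_externals_absent(self):
        names = list_backends()
        for b in ("deflate", "bzip2", "lzma", "ctx", "ctx-rc"):
            assert b in names
        assert "zpaq" not in names and "mbgc" not in names

    def test_register_nonexistent_binary_fails(self, tmp_path):
        with pytest.raises(BackendError):
            register_external_backend("zpaq", tmp_path / "no-such-binary")
        with pytest.raises(BackendError):
            register_external_backend("unknown-tool", "/bin/sh")

    def test_unknown_backend_errors(self):
        with pytest.raises(BackendError):
            compress_ratio("ACGT" * 100, "zpaq")

    def test_ratio_bookkeeping_is_exact(self):
        res = compress_ratio("ACGT" * 500, "deflate")
        assert isinstance(res.input_bases, int) and isinstance(res.compressed_bytes, int)
        assert res.ratio == res.input_bases / res.compressed_bytes

    def test_nonpositive_compressed_size_rejected(self):
        with pytest.raises(ValueError):
            CompressionResult("x", 10, 0)

    def test_backend_config_mismatch(self):
        with pytest.raises(ValueError):
            compress_ratio("ACGT" * 10, "ctx", ContextModelConfig(rc_canonical=True))


class TestCodeLengths:
    def test_homopolymer_converges_to_near_zero_bits(self):
        res = compress_ratio("A" * 100_000, "ctx")
        assert res.ratio > 100

    def test_order0_uniform_within_one_percent_of_entropy(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        res = compress_ratio(seq, "ctx", ContextModelConfig(order=0))
        assert res.bits_per_base == pytest.approx(2.0, rel=0.01)

    def test_uniform_respects_source_coding_floor(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        res = compress_ratio(seq, "ctx")
        assert res.bits_per_base >= 1.99


class TestRcMechanism:
    def test_sequence_plus_its_reverse_complement(self):
        """Statistics learned on S transfer to reverse_complement(S) only
        under the canonical model: its output is smaller on S + rc(S)."""
        plain_sizes, rc_sizes = [], []
        for seed in range(5):
            g = generate_genome(
                GenomeSpec(length=100_000, bias_strength=0.5, seed=500 + seed)
            )
            doubled = (g.sequence + reverse_complement(g.sequence)).encode()
            plain_sizes.append(len(context_encode(doubled, ContextModelConfig())))
            rc_sizes.append(
                len(context_encode(doubled, ContextModelConfig(rc_canonical=True)))
            )
        assert np.mean(rc_sizes) < np.mean(plain_sizes)

    def test_redundancy_monotonicity_every_backend(self):
        """Mean compression ratio rises with planted repeat density for all
        built-in backends."""
        densities = (0.0, 0.3, 0.6)
        means = {b: [] for b in ("deflate", "bzip2", "lzma", "ctx", "ctx-rc")}
        for rf in densities:
            ratios = {b: [] for b in means}
            for seed in range(5):
                g = generate_genome(
                    GenomeSpec(length=30_000, repeat_fraction=rf, seed=700 + seed)
                )
                stream = sequence_to_stream(g.sequence)
                for b in means:
                    ratios[b].append(compress_ratio(stream, b).ratio)
            for b in means:
                means[b].append(np.mean(ratios[b]))
        for b, curve in means.items():
            assert curve[0] < curve[1] < curve[2], (b, curve)

    def test_canonical_gain_requires_inverted_repeats(self):
        """ctx-rc beats ctx when repeats are reverse-complemented copies,
        and shows no advantage when the same repeats are direct copies."""
        inv_gain, tandem_gain = [], []
        for seed in range(5):
            for frac, sink in ((1.0, inv_gain), (0.0, tandem_gain)):
                g = generate_genome(
                    GenomeSpec(
                        length=60_000,
                        repeat_fraction=0.4,
                        inverted_repeat_fraction=frac,
                        seed=900 + seed,
                    )
                )
                stream = sequence_to_stream(g.sequence)
                rp = compress_ratio(stream, "ctx").ratio
                rr = compress_ratio(stream, "ctx-rc").ratio
                sink.append((rr - rp) / rp)
        assert np.mean(inv_gain) > 0.02
        assert np.mean(tandem_gain) <= 0.0
        assert max(abs(d) for d in tandem_gain) < 0.05
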