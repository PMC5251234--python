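"""Wavelet decomposition and the multi-scale Pearson similarity."""

import numpy as np
import pytest

from tvcurve import (
    RnaRecord,
    SimilarityConfig,
    encode_tvcurve,
    multiscale_similarity,
    resample_signal,
    similarity_to_distance,
    wavelet_decompose,
)

from .conftest import random_record
from .oracles import oracle_multiscale_similarity


class TestResample:
    def test_identity_when_lengths_match(self):
        sig = np.array([3.0, 1.0, 4.0, 1.0])
        assert np.array_equal(resample_signal(sig, 4), sig)

    def test_constant_signal_stays_constant(self):
        assert np.allclose(resample_signal(np.full(5, 2.5), 16), 2.5)

    def test_ramp_closed_form(self):
        out = resample_signal(np.array([0.0, 1.0, 2.0, 3.0]), 7)
        assert np.allclose(out, [0, 0.5, 1, 1.5, 2, 2.5, 3])

    def test_endpoints_preserved(self, rng):
        sig = rng.normal(size=11)
        out = resample_signal(sig, 64)
        assert out[0] == sig[0] and out[-1] == sig[-1]

    def test_degenerate_lengths_rejected(self):
        with pytest.raises(ValueError):
            resample_signal(np.array([1.0]), 8)


class TestWaveletDecompose:
    def test_constant_signal_has_zero_details(self):
        dec = wavelet_decompose(np.full(16, 3.0), SimilarityConfig(levels=4))
        assert all(np.allclose(d, 0) for d in dec.details)

    def test_two_sample_haar_closed_form(self):
        dec = wavelet_decompose(np.array([1.0, -1.0]), SimilarityConfig(levels=1))
        assert np.allclose(dec.approx, [0.0])
        assert np.allclose(dec.details[0], [np.sqrt(2)])

    def test_dyadic_coefficient_lengths(self):
        dec = wavelet_decompose(np.arange(32.0), SimilarityConfig(levels=4))
        assert [len(d) for d in dec.details] == [16, 8, 4, 2]
        assert len(dec.approx) == 2

    def test_roundtrip_reconstruction(self, rng):
        sig = rng.normal(size=64)
        dec = wavelet_decompose(sig, SimilarityConfig(levels=4))
        assert np.max(np.abs(dec.reconstruct() - sig)) <= 1e-9

    def test_too_deep_level_reduced_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            dec = wavelet_decompose(np.arange(8.0), SimilarityConfig(levels=6))
        assert dec.levels == 3
        assert "too deep" in caplog.text


class TestMultiscaleSimilarity:
    def test_self_similarity_is_exactly_one(self, backend, rng):
        rec = random_record(rng, 33, backend=backend)
        curve = encode_tvcurve(rec)
        assert multiscale_similarity(curve, curve) == 1.0
        assert similarity_to_distance(multiscale_similarity(curve, curve)) == 0.0

    def test_symmetry_is_exact(self, backend, rng):
        for _ in range(10):
            a = encode_tvcurve(random_record(rng, int(rng.integers(10, 50)), "a", backend))
            b = encode_tvcurve(random_record(rng, int(rng.integers(10, 50)), "b", backend))
            assert multiscale_similarity(a, b) == multiscale_similarity(b, a)

    def test_score_bounded(self, backend, rng):
        for _ in range(10):
            a = encode_tvcurve(random_record(rng, 20, "a", backend))
            b = encode_tvcurve(random_record(rng, 31, "b", backend))
            assert -1.0 <= multiscale_similarity(a, b) <= 1.0

    def test_weight_rescaling_invariance(self, backend, rng):
        a = encode_tvcurve(random_record(rng, 24, "a", backend))
        b = encode_tvcurve(random_record(rng, 24, "b", backend))
        w = [1.0, 2.0, 3.0, 4.0, 5.0]
        scaled = [40 * x for x in w]
        s1 = multiscale_similarity(a, b, SimilarityConfig(weights=w))
        s2 = multiscale_similarity(a, b, SimilarityConfig(weights=scaled))
        assert abs(s1 - s2) <= 1e-12

    def test_degenerate_all_a_sequences(self):
        # both curves are straight ramps: every detail level is (0, 0, ...)
        a = encode_tvcurve(RnaRecord(id="a", sequence="A" * 12, structure="." * 12))
        b = encode_tvcurve(RnaRecord(id="b", sequence="A" * 12, structure="." * 12))
        assert multiscale_similarity(a, b) == 1.0

    @pytest.mark.parametrize("kind", ["cumulative", "steps"])
    def test_matches_from_definition_oracle(self, backend, rng, kind):
        """>= 20 random pairs, lengths 10-64, agree with the straight-line
        re-computation to 1e-9."""
        cfg = SimilarityConfig(signal_kind=kind)
        for _ in range(22):
            ra = random_record(rng, int(rng.integers(10, 65)), "a", backend)
            rb = random_record(rng, int(rng.integers(10, 65)), "b", backend)
            got = multiscale_similarity(encode_tvcurve(ra), encode_tvcurve(rb), cfg)
            want = oracle_multiscale_similarity(
                ra.sequence, ra.structure, rb.sequence, rb.structure, kind=kind
            )
            assert got == pytest.approx(want, abs=1e-9)

    def test_local_perturbation_hits_fine_scales_hardest(self):
        """Swapping A<->U at one unpaired site bumps a single curve ordinate:
        the finest detail correlation must drop more than the
        approximation correlation (global vs local sensitivity)."""
        n = 64
        rng = np.random.default_rng(7)
        base = list("".join(rng.choice(list("ACGU"), size=n)))
        base[32] = "A"
        seq_a = "".join(base)
        base[32] = "U"
        seq_b = "".join(base)
        db = "." * n
        cfg = SimilarityConfig()
        a = encode_tvcurve(RnaRecord(id="a", sequence=seq_a, structure=db))
        b = encode_tvcurve(RnaRecord(id="b", sequence=seq_b, structure=db))
        dec_a = wavelet_decompose(a.signal(), cfg)
        dec_b = wavelet_decompose(b.signal(), cfg)

        def corr(u, v):
            if np.all(u == u[0]) or np.all(v == v[0]):
                return 1.0 if np.array_equal(u, v) else 0.0
            return float(np.corrcoef(u, v)[0, 1])

        drop_approx = 1.0 - corr(dec_a.approx, dec_b.approx)
        drop_fine = 1.0 - corr(dec_a.details[0], dec_b.details[0])
        assert drop_fine > drop_approx


class TestConfigValidation:
    def test_default_levels_and_uniform_weights(self):
        cfg = SimilarityConfig()
        assert cfg.levels == 4
        assert np.allclose(cfg.normalized_weights(), 0.2)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"levels": 0},
            {"signal_kind": "fourier"},
            {"weights": [1, 1]},
            {"weights": [-1, 1, 1, 1, 1]},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimilarityConfig(**kwargs)
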