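"""Signature refitting: NNLS exposures, invariances, etiology summaries."""

import itertools

import numpy as np
import pytest

from sarcosig.signatures import (SignatureMatrix, etiology_summary,
                                 fit_exposures, read_signature_matrix,
                                 write_signature_matrix)
from sarcosig.spectrum import CHANNELS_96, MutationSpectrum
from sarcosig.synthetic import SYNTHETIC_ETIOLOGY_MAP
from sarcosig.variant_io import ConfigurationError


def _spectrum(channels, sample="S1"):
    channels = np.asarray(channels)
    return MutationSpectrum(sample_id=sample, raw12=np.zeros(12, dtype=int),
                            channels96=channels.astype(np.int64),
                            n_snv=int(channels.sum()), n_no_context=0)


def _sub_matrix(matrix, names):
    idx = [list(matrix.names).index(n) for n in names]
    w = matrix.weights[:, idx]
    return SignatureMatrix(channels=matrix.channels, names=tuple(names),
                           weights=w / w.sum(axis=0))


def test_matrix_validation():
    w = np.full((96, 2), 1 / 96)
    SignatureMatrix(channels=tuple(CHANNELS_96), names=("a", "b"), weights=w)
    with pytest.raises(ConfigurationError, match="sum to 1"):
        SignatureMatrix(channels=tuple(CHANNELS_96), names=("a",),
                        weights=np.full((96, 1), 1 / 90))
    bad = w.copy()
    bad[0, 0] = -bad[0, 0]
    with pytest.raises(ConfigurationError, match="nonnegative"):
        SignatureMatrix(channels=tuple(CHANNELS_96), names=("a", "b"),
                        weights=bad)
    with pytest.raises(ConfigurationError, match="no signatures"):
        SignatureMatrix(channels=tuple(CHANNELS_96), names=(),
                        weights=np.zeros((96, 0)))


def test_matrix_round_trip(tmp_path, synthetic_matrix):
    p = tmp_path / "sigs.tsv"
    write_signature_matrix(synthetic_matrix, p)
    back = read_signature_matrix(p)
    assert back.names == synthetic_matrix.names
    np.testing.assert_allclose(back.weights, synthetic_matrix.weights)


def test_identity_recovery(synthetic_matrix):
    """A spectrum equal to one signature column recovers that signature."""
    col = synthetic_matrix.weights[:, 0]
    profile = fit_exposures(_spectrum(np.round(col * 100000)), synthetic_matrix)
    assert profile.exposures[synthetic_matrix.names[0]] == pytest.approx(1.0)
    assert profile.reconstruction_cosine == pytest.approx(1.0, abs=1e-3)


def test_two_signature_mixture_recovery(synthetic_matrix):
    """0.7/0.3 mixture of two well-separated signatures, 5000 mutations,
    recovered within +/-0.05."""
    sub = _sub_matrix(synthetic_matrix, ["AGING", "APOBEC"])
    a, b = sub.weights[:, 0], sub.weights[:, 1]
    cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
    assert cos < 0.3  # well separated
    rng = np.random.default_rng(17)
    draws = rng.choice(96, size=5000, p=0.7 * a + 0.3 * b)
    counts = np.bincount(draws, minlength=96)
    profile = fit_exposures(_spectrum(counts), synthetic_matrix)
    assert profile.exposures["AGING"] == pytest.approx(0.7, abs=0.05)
    assert profile.exposures["APOBEC"] == pytest.approx(0.3, abs=0.05)


def test_nnls_beats_brute_force_grid(synthetic_matrix):
    """On K=3 references, NNLS attains a residual no worse than exhaustive
    search over the 5-point exposure simplex grid."""
    sub = _sub_matrix(synthetic_matrix, ["AGING", "UV", "MMR"])
    rng = np.random.default_rng(23)
    for _ in range(5):
        mix = rng.dirichlet([1, 1, 1])
        counts = np.bincount(rng.choice(96, size=800, p=sub.weights @ mix),
                             minlength=96)
        target = counts / counts.sum()
        from scipy.optimize import nnls
        coef, resid = nnls(sub.weights, target)
        grid_best = min(
            np.linalg.norm(sub.weights @ (np.array(g) / 4) - target)
            for g in itertools.product(range(5), repeat=3) if sum(g) == 4)
        assert resid <= grid_best + 1e-12


def test_column_permutation_invariance(synthetic_matrix):
    rng = np.random.default_rng(31)
    counts = np.bincount(rng.choice(96, size=2000,
                                    p=synthetic_matrix.weights[:, 1]),
                         minlength=96)
    base = fit_exposures(_spectrum(counts), synthetic_matrix)
    perm = list(reversed(range(synthetic_matrix.k)))
    permuted = SignatureMatrix(
        channels=synthetic_matrix.channels,
        names=tuple(synthetic_matrix.names[j] for j in perm),
        weights=synthetic_matrix.weights[:, perm])
    other = fit_exposures(_spectrum(counts), permuted)
    for name in synthetic_matrix.names:
        assert other.exposures[name] == pytest.approx(base.exposures[name])


def test_scale_invariance_and_normalisation(synthetic_matrix):
    rng = np.random.default_rng(37)
    counts = np.bincount(rng.choice(96, size=1500,
                                    p=synthetic_matrix.weights[:, 2]),
                         minlength=96)
    p1 = fit_exposures(_spectrum(counts), synthetic_matrix)
    p2 = fit_exposures(_spectrum(counts * 2), synthetic_matrix)
    for name in synthetic_matrix.names:
        assert p2.exposures[name] == pytest.approx(p1.exposures[name])
    assert sum(p1.exposures.values()) == pytest.approx(1.0)


def test_min_exposure_thresholding(synthetic_matrix):
    rng = np.random.default_rng(41)
    counts = np.bincount(rng.choice(96, size=3000,
                                    p=synthetic_matrix.weights[:, 0]),
                         minlength=96)
    profile = fit_exposures(_spectrum(counts), synthetic_matrix,
                            min_exposure=0.06)
    vals = np.array(list(profile.exposures.values()))
    assert ((vals == 0) | (vals >= 0.06)).all()
    assert vals.sum() == pytest.approx(1.0)


def test_all_zero_spectrum_flagged(synthetic_matrix):
    profile = fit_exposures(_spectrum(np.zeros(96)), synthetic_matrix)
    assert not profile.defined and profile.low_confidence


def test_low_confidence_flag(synthetic_matrix):
    counts = np.zeros(96)
    counts[0] = 10  # below the default min_snv of 50
    assert fit_exposures(_spectrum(counts), synthetic_matrix).low_confidence


def test_etiology_summary(synthetic_matrix):
    p1 = fit_exposures(
        _spectrum(np.round(synthetic_matrix.weights[:, 0] * 10000)),
        synthetic_matrix)
    df = etiology_summary([p1], SYNTHETIC_ETIOLOGY_MAP)
    assert df.loc[0, "aging"] == pytest.approx(1.0)
    assert df.loc[0, "UV"] == pytest.approx(0.0)

    two_uv = {"sigA": "UV", "sigB": "UV"}
    fake = type(p1)(sample_id="X", exposures={"sigA": 0.6, "sigB": 0.4},
                    reconstruction_cosine=1.0, n_snv_used=100,
                    low_confidence=False)
    df = etiology_summary([fake], two_uv)
    assert df.loc[0, "UV"] == pytest.approx(1.0)

    with pytest.raises(ConfigurationError, match="etiology"):
        etiology_summary([fake], {"sigA": "UV"})
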