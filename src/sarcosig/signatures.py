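"""Mutational-signature refitting by nonnegative least squares.

A reference matrix of K signatures (96 channels each, columns summing to
one — COSMIC v2 layout) is fitted to each sample's normalised 96-channel
spectrum with NNLS. Exposures are normalised to sum to one, small
exposures (below ``min_exposure``, default 0.06 after the deconstructSigs
convention) are zeroed and the remainder renormalised, so each value is a
"probability" in [0, 1] that the corresponding mutational process
contributed the sample's mutations. Reconstruction quality is reported as
the cosine similarity between the observed spectrum and the thresholded
reconstruction.

Samples with fewer usable mutations than ``min_snv`` (default 50) still
get a profile, flagged low-confidence rather than suppressed — small
cohorts routinely contain samples with only a handful of mutations.

Etiology summaries sum the exposures of signatures sharing an annotation
(aging/CpG, UV, MMR/MSI, APOBEC, POLE, POLH, ...), clipped to [0, 1]. A
COSMIC v2 annotation map ships as editable YAML
(``data/etiology_cosmic_v2.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import nnls

from .spectrum import CHANNELS_96, MutationSpectrum
from .variant_io import ConfigurationError

_COLSUM_TOL = 1e-8


@dataclass(slots=True)
class SignatureMatrix:
    """96 x K nonnegative reference matrix; columns are unit-sum signatures."""

    channels: tuple[str, ...]
    names: tuple[str, ...]
    weights: np.ndarray  # shape (96, K)

    def __post_init__(self):
        self.channels = tuple(self.channels)
        self.names = tuple(self.names)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.channels != tuple(CHANNELS_96):
            raise ConfigurationError("signature matrix channels must be the "
                                     "96 canonical labels in canonical order")
        if self.weights.shape != (96, len(self.names)):
            raise ConfigurationError("signature matrix shape mismatch")
        if self.weights.shape[1] == 0:
            raise ConfigurationError("signature matrix has no signatures")
        if (self.weights < 0).any():
            raise ConfigurationError("signature matrix entries must be nonnegative")
        colsums = self.weights.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            raise ConfigurationError("signature matrix columns must sum to 1")

    @property
    def k(self) -> int:
        return len(self.names)


def read_signature_matrix(path) -> SignatureMatrix:
    """Read a signature matrix TSV: first column the 96 channel labels
    (``A[C>A]A`` naming), remaining columns one signature each. Rows may
    appear in any order; they are sorted into canonical channel order."""
    df = pd.read_csv(path, sep="\t")
    label_col = df.columns[0]
    df = df.set_index(label_col)
    missing = set(CHANNELS_96) - set(df.index)
    if missing:
        raise ConfigurationError(f"signature matrix missing channels, e.g. "
                                 f"{sorted(missing)[:3]}")
    df = df.loc[list(CHANNELS_96)]
    return SignatureMatrix(channels=tuple(CHANNELS_96),
                           names=tuple(str(c) for c in df.columns),
                           weights=df.to_numpy(dtype=float))


def write_signature_matrix(matrix: SignatureMatrix, path) -> None:
    df = pd.DataFrame(matrix.weights, index=list(matrix.channels),
                      columns=list(matrix.names))
    df.index.name = "channel"
    df.to_csv(path, sep="\t", lineterminator="\n")


@dataclass(slots=True)
class ExposureProfile:
    """Fitted signature exposures ("probabilities") for one sample."""

    sample_id: str
    exposures: dict[str, float]
    reconstruction_cosine: float
    n_snv_used: int
    low_confidence: bool
    defined: bool = True  # False for all-zero spectra

    def top_signature(self) -> str:
        return max(self.exposures, key=lambda k: (self.exposures[k], k))


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def fit_exposures(spectrum: MutationSpectrum, matrix: SignatureMatrix,
                  min_exposure: float = 0.06,
                  min_snv: int = 50) -> ExposureProfile:
    """Fit one sample's 96-channel spectrum against the reference matrix.

    The spectrum is normalised to frequencies (making the fit invariant to
    total mutation count), solved by NNLS, thresholded and renormalised.
    An all-zero spectrum yields a flagged undefined profile.
    """
    counts = np.asarray(spectrum.channels96, dtype=float)
    total = counts.sum()
    if total == 0:
        return ExposureProfile(
            sample_id=spectrum.sample_id,
            exposures={n: float("nan") for n in matrix.names},
            reconstruction_cosine=float("nan"), n_snv_used=0,
            low_confidence=True, defined=False)

    target = counts / total
    coef, _ = nnls(matrix.weights, target)
    if coef.sum() == 0:
        exposures = np.zeros(matrix.k)
    else:
        exposures = coef / coef.sum()
        exposures[exposures < min_exposure] = 0.0
        s = exposures.sum()
        exposures = exposures / s if s > 0 else exposures

    recon = matrix.weights @ exposures
    return ExposureProfile(
        sample_id=spectrum.sample_id,
        exposures={n: float(e) for n, e in zip(matrix.names, exposures)},
        reconstruction_cosine=_cosine(target, recon),
        n_snv_used=int(total),
        low_confidence=total < min_snv,
    )


def fit_cohort(spectra: dict[str, MutationSpectrum], matrix: SignatureMatrix,
               min_exposure: float = 0.06,
               min_snv: int = 50) -> list[ExposureProfile]:
    return [fit_exposures(sp, matrix, min_exposure=min_exposure,
                          min_snv=min_snv) for sp in spectra.values()]


def load_etiology_map(path=None) -> dict[str, str]:
    """Signature name -> etiology label. Defaults to the shipped COSMIC v2
    annotation."""
    if path is None:
        text = resources.files("sarcosig.data").joinpath(
            "etiology_cosmic_v2.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return {str(k): str(v) for k, v in raw.items()}


def etiology_summary(profiles: list[ExposureProfile],
                     etiology_map: dict[str, str]) -> pd.DataFrame:
    """Per-sample etiology probabilities: sum of member-signature exposures,
    clipped to [0, 1]. Sample x etiology layout (etiologies sorted).
    Unmapped signatures are a configuration error."""
    etiologies = sorted(set(etiology_map.values()))
    rows = []
    for p in profiles:
        unmapped = set(p.exposures) - set(etiology_map)
        if unmapped:
            raise ConfigurationError(
                f"signatures without etiology annotation: {sorted(unmapped)}")
        row = {"sample": p.sample_id}
        for et in etiologies:
            val = sum(v for s, v in p.exposures.items()
                      if etiology_map[s] == et)
            row[et] = float(np.clip(val, 0.0, 1.0))
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample", *etiologies])


def exposures_frame(profiles: list[ExposureProfile]) -> pd.DataFrame:
    """Sample x signature exposure table with fit diagnostics."""
    if not profiles:
        return pd.DataFrame(columns=["sample"])
    names = list(profiles[0].exposures)
    rows = []
    for p in profiles:
        row = {"sample": p.sample_id}
        row.update(p.exposures)
        row["reconstruction_cosine"] = p.reconstruction_cosine
        row["n_snv_used"] = p.n_snv_used
        row["low_confidence"] = p.low_confidence
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample", *names,
                                       "reconstruction_cosine", "n_snv_used",
                                       "low_confidence"])
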