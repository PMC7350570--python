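"""Substitution-class and trinucleotide-context spectra.

Two resolutions are produced per sample:

* the 12 raw ordered substitution classes (``A>C`` ... ``T>G``), with no
  strand collapsing — transitions on either strand (e.g. ``G>A`` versus
  ``C>T``) are reported separately;
* the standard 96-channel spectrum: substitutions collapsed onto the
  pyrimidine strand (6 types) crossed with the 5' and 3' flanking bases,
  labelled ``A[C>T]G`` style.

Channel order is fixed (substitution-major, then 5' base, then 3' base,
alphabetical) so spectrum files are comparable bit-for-bit. Variants
without a valid trinucleotide context contribute to the 12-class counts
but not to the 96 channels; their number is tracked per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import NUCLEOTIDES, VariantRecord

BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

#: the 12 raw ordered substitution classes
RAW12_CLASSES = tuple(f"{r}>{a}" for r in BASES for a in BASES if r != a)

#: the 6 pyrimidine-strand substitution types
PYRIMIDINE_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: fixed 96-channel label order, "A[C>A]A" style
CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in PYRIMIDINE_SUBS for five in BASES for three in BASES
)

_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS_96)}
_RAW12_INDEX = {label: i for i, label in enumerate(RAW12_CLASSES)}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class ClassificationError(ValueError):
    """Raised for alleles that do not form a single-nucleotide substitution."""


def classify_substitution(ref: str, alt: str) -> str:
    """Return the raw ordered substitution class, e.g. ``("G","A") -> "G>A"``."""
    if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
        raise ClassificationError(f"not a single-nucleotide substitution: {ref}>{alt}")
    if ref == alt:
        raise ClassificationError("ref and alt are identical")
    return f"{ref}>{alt}"


def collapse_to_pyrimidine(ref: str, alt: str, context: str) -> tuple[str, str]:
    """Collapse a substitution-with-context onto the pyrimidine strand.

    Purine reference bases are reverse-complemented together with their
    context so that the returned context's middle base is C or T.
    """
    if len(context) != 3 or any(b not in NUCLEOTIDES for b in context):
        raise ClassificationError(f"invalid context {context!r}")
    if context[1] != ref:
        raise ClassificationError("context middle base does not match ref")
    sub = classify_substitution(ref, alt)
    if ref in "CT":
        return sub, context
    rc = reverse_complement(context)
    return f"{rc[1]}>{alt.translate(_COMP)}", rc


def channel_label(ref: str, alt: str, context: str) -> str:
    sub, ctx = collapse_to_pyrimidine(ref, alt, context)
    return f"{ctx[0]}[{sub}]{ctx[2]}"


@dataclass(slots=True)
class MutationSpectrum:
    """Per-sample substitution counts at 12-class and 96-channel resolution."""

    sample_id: str
    raw12: np.ndarray       # int counts, order RAW12_CLASSES
    channels96: np.ndarray  # int counts, order CHANNELS_96
    n_snv: int
    n_no_context: int       # SNVs lacking a usable trinucleotide context

    def raw12_count(self, label: str) -> int:
        return int(self.raw12[_RAW12_INDEX[label]])

    def channel_count(self, label: str) -> int:
        return int(self.channels96[_CHANNEL_INDEX[label]])


def build_spectra(variants: list[VariantRecord],
                  samples: list[str] | None = None) -> dict[str, MutationSpectrum]:
    """Build one :class:`MutationSpectrum` per sample.

    Every SNV contributes to exactly one 12-class cell; SNVs with a valid
    context contribute to exactly one of the 96 channels. Indels are
    ignored. ``samples`` forces the output sample set (zero-variant
    samples yield all-zero spectra); otherwise samples appear in order of
    first occurrence in the input.
    """
    order: list[str] = list(samples) if samples is not None else []
    seen = set(order)
    raw = {s: np.zeros(12, dtype=np.int64) for s in order}
    chan = {s: np.zeros(96, dtype=np.int64) for s in order}
    nsnv = {s: 0 for s in order}
    noctx = {s: 0 for s in order}

    for v in variants:
        s = v.sample_id
        if s not in seen:
            if samples is not None:
                raise KeyError(f"variant sample {s!r} not in the requested sample list")
            seen.add(s)
            order.append(s)
            raw[s] = np.zeros(12, dtype=np.int64)
            chan[s] = np.zeros(96, dtype=np.int64)
            nsnv[s] = 0
            noctx[s] = 0
        if not v.is_snv:
            continue
        raw[s][_RAW12_INDEX[classify_substitution(v.ref, v.alt)]] += 1
        nsnv[s] += 1
        if v.context is None:
            noctx[s] += 1
            continue
        try:
            chan[s][_CHANNEL_INDEX[channel_label(v.ref, v.alt, v.context)]] += 1
        except ClassificationError:
            noctx[s] += 1

    return {
        s: MutationSpectrum(s, raw[s], chan[s], nsnv[s], noctx[s])
        for s in order
    }


def spectra_frame(spectra: dict[str, MutationSpectrum]) -> pd.DataFrame:
    """One row per sample: 96 channel columns, 12 raw columns, n_snv,
    n_no_context — the canonical spectrum TSV layout."""
    rows = []
    for s, sp in spectra.items():
        row = {"sample": s}
        row.update({lab: int(c) for lab, c in zip(CHANNELS_96, sp.channels96)})
        row.update({lab: int(c) for lab, c in zip(RAW12_CLASSES, sp.raw12)})
        row["n_snv"] = sp.n_snv
        row["n_no_context"] = sp.n_no_context
        rows.append(row)
    cols = ["sample", *CHANNELS_96, *RAW12_CLASSES, "n_snv", "n_no_context"]
    return pd.DataFrame(rows, columns=cols)


def cohort_raw12(spectra: dict[str, MutationSpectrum]) -> dict[str, int]:
    """Cohort-level totals over the 12 raw substitution classes."""
    total = np.zeros(12, dtype=np.int64)
    for sp in spectra.values():
        total += sp.raw12
    return {lab: int(c) for lab, c in zip(RAW12_CLASSES, total)}
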