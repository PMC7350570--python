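"""Kyte-Doolittle hydrophobicity shifts of missense changes.

Each missense variant is scored by the change in Kyte-Doolittle (1982)
hydropathy between the reference and alternate residue,
``delta = KD(alt) - KD(ref)``; positive values mean the mutant peptide is
more hydrophobic, a property associated with greater immunogenicity. The
cohort-level statistic is the mean delta with a t-based 95% confidence
interval and the p-value of a paired t test of alternate- versus
reference-residue hydropathy — computed, equivalently, as a one-sample t
test of the deltas against zero.

The scale ships as a plain TSV resource (``data/kd_scale.tsv``) so it is
auditable and replaceable; hydrophobic residues have index > 0, with
isoleucine (+4.5) the most hydrophobic and arginine (-4.5) the least.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

from scipy import stats

from .variant_io import STANDARD_AA, VariantRecord

logger = logging.getLogger(__name__)


def _load_scale() -> dict[str, float]:
    text = resources.files("sarcosig.data").joinpath("kd_scale.tsv").read_text()
    scale: dict[str, float] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        aa, value = line.split("\t")
        scale[aa] = float(value)
    if set(scale) != STANDARD_AA:
        raise ValueError("Kyte-Doolittle scale resource must cover exactly the "
                         "20 standard amino acids")
    return scale


#: Kyte-Doolittle hydropathy index, 1-letter amino acid -> value
KD_SCALE: dict[str, float] = _load_scale()


def kd_delta(ref_aa: str, alt_aa: str) -> float:
    """Hydropathy shift ``KD(alt) - KD(ref)``; antisymmetric in its arguments.

    Raises ``KeyError`` for non-standard residues (U, B, Z, X, stop), which
    callers exclude with a logged count.
    """
    return KD_SCALE[alt_aa] - KD_SCALE[ref_aa]


def collect_deltas(variants: list[VariantRecord],
                   include_silent: bool = False) -> tuple[list[float], int]:
    """Per-variant hydropathy deltas over missense changes.

    Silent variants contribute ``0.0`` only when ``include_silent`` is set
    (the shift statistic is defined over missense changes by default).
    Returns ``(deltas, n_excluded)`` where the excluded count covers
    missense records with non-standard residues.
    """
    deltas: list[float] = []
    n_excluded = 0
    for v in variants:
        if v.consequence == "missense":
            if (v.ref_aa in KD_SCALE) and (v.alt_aa in KD_SCALE):
                deltas.append(kd_delta(v.ref_aa, v.alt_aa))
            else:
                n_excluded += 1
        elif include_silent and v.consequence == "silent":
            deltas.append(0.0)
    if n_excluded:
        logger.info("excluded %d missense variants with non-standard residues",
                    n_excluded)
    return deltas, n_excluded


@dataclass(slots=True)
class HydrophobicityReport:
    """Cohort hydrophobicity-shift statistic."""

    n: int
    n_increasing: int        # deltas strictly > 0
    mean_delta: float
    ci95: tuple[float, float]
    p_paired: float
    t_statistic: float
    ci_defined: bool

    @property
    def frac_increasing(self) -> float:
        return self.n_increasing / self.n if self.n else math.nan


def cohort_shift(deltas: list[float], alpha: float = 0.05) -> HydrophobicityReport:
    """Mean shift, t-based CI and paired-test p-value for a delta vector.

    With a single observation the CI and p-value are undefined and flagged
    via ``ci_defined=False``. All fields are invariant to the order of
    ``deltas``.
    """
    if not deltas:
        raise ValueError("cohort_shift requires a non-empty delta list")
    n = len(deltas)
    n_inc = sum(1 for d in deltas if d > 0)
    mean = float(sum(deltas) / n)
    if n == 1:
        return HydrophobicityReport(n, n_inc, mean, (math.nan, math.nan),
                                    math.nan, math.nan, ci_defined=False)
    res = stats.ttest_1samp(deltas, popmean=0.0)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return HydrophobicityReport(
        n=n, n_increasing=n_inc, mean_delta=mean,
        ci95=(float(ci.low), float(ci.high)),
        p_paired=float(res.pvalue), t_statistic=float(res.statistic),
        ci_defined=True,
    )


def shift_report(variants: list[VariantRecord],
                 include_silent: bool = False) -> tuple[HydrophobicityReport, int]:
    """Convenience wrapper: collect deltas from records and summarise."""
    deltas, n_excluded = collect_deltas(variants, include_silent=include_silent)
    return cohort_shift(deltas), n_excluded
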