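"""Synthetic somatic-variant cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes, so every stage is testable without external downloads:

* per-sample mutation burden drawn from a site-group-specific log-normal
  truncated below at a hard minimum (exome cohorts are heavy-tailed;
  cutaneous head/neck tumours carry far more mutations than visceral
  ones);
* each variant's 96-channel trinucleotide class drawn from the sample's
  mixture of signature columns, then placed on either strand with equal
  probability (contexts come from the channel draw — no reference genome
  needed);
* consequence classes drawn from fixed proportions;
* missense amino-acid pairs drawn from the single-nucleotide-accessible
  substitution table of the standard genetic code, exponentially tilted
  so the expected Kyte-Doolittle shift equals ``hydro_bias``.

The default :class:`CohortSpec` emulates a 48-sample angiosarcoma-like
whole-exome cohort: 36 patients, 11 UV-dominated face/scalp samples with
high burden (expected group mean 925 mutations), 37 lower-burden samples
(expected mean 63, aging/CpG-dominated, a few visceral samples enriched
for mismatch-repair deficiency), missense/silent fractions 0.61/0.31 and
a mean hydrophobicity shift of +0.9240.

Everything is deterministic given the seed; the ground-truth record keeps
every latent draw so any generated variant can be audited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .hydrophobicity import KD_SCALE
from .signatures import SignatureMatrix
from .spectrum import BASES, CHANNELS_96, PYRIMIDINE_SUBS, reverse_complement
from .variant_io import STOP, SampleMeta, VariantRecord

# ---------------------------------------------------------------------------
# Synthetic signature reference (labelled synthetic: idealised etiology
# profiles, not the empirical COSMIC catalogue)

_BG = {  # background mass spread uniformly over all 96 channels
    "AGING": 0.20, "UV": 0.15, "MMR": 0.20, "APOBEC": 0.15, "POLE": 0.25,
}

SYNTHETIC_ETIOLOGY_MAP = {
    "AGING": "aging", "UV": "UV", "MMR": "MMR",
    "APOBEC": "APOBEC", "POLE": "POLE",
}


def _channel_index(five: str, sub: str, three: str) -> int:
    return CHANNELS_96.index(f"{five}[{sub}]{three}")


def synthetic_signature_matrix() -> SignatureMatrix:
    """A 5-signature synthetic reference with etiology-shaped profiles.

    AGING: C>T at NpCpG (spontaneous 5-methylcytosine deamination);
    UV: C>T at dipyrimidines (5' C/T, T favoured); MMR: mixed C>T/T>C;
    APOBEC: C>T and C>G at TpCpW; POLE: C>A at TpCpT plus T>G at TpTpT.
    Each signature carries a small uniform background so no channel has
    probability zero.
    """
    cols = {}

    w = np.zeros(96)
    for five in BASES:
        w[_channel_index(five, "C>T", "G")] = 1.0
    cols["AGING"] = w

    w = np.zeros(96)
    for five, weight in (("T", 2.0), ("C", 1.0)):
        for three in BASES:
            w[_channel_index(five, "C>T", three)] = weight
    cols["UV"] = w

    w = np.zeros(96)
    for five in BASES:
        for three in BASES:
            w[_channel_index(five, "C>T", three)] += 0.35 / 16
            w[_channel_index(five, "T>C", three)] += 0.45 / 16
    cols["MMR"] = w

    w = np.zeros(96)
    for sub in ("C>T", "C>G"):
        for three in ("A", "T"):
            w[_channel_index("T", sub, three)] = 1.0
    cols["APOBEC"] = w

    w = np.zeros(96)
    w[_channel_index("T", "C>A", "T")] = 2.0
    w[_channel_index("T", "T>G", "T")] = 1.0
    cols["POLE"] = w

    names = tuple(cols)
    weights = np.empty((96, len(names)))
    for j, name in enumerate(names):
        col = cols[name]
        col = col / col.sum() * (1.0 - _BG[name])
        col = col + _BG[name] / 96.0
        weights[:, j] = col
    return SignatureMatrix(channels=tuple(CHANNELS_96), names=names,
                           weights=weights)


# ---------------------------------------------------------------------------
# Amino-acid substitution table (single-nucleotide-accessible, KD-tilted)

_CODON_BASES = "TCAG"
_CODON_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRR"
             "IIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
GENETIC_CODE = {
    a + b + c: _CODON_AA[16 * i + 4 * j + k]
    for i, a in enumerate(_CODON_BASES)
    for j, b in enumerate(_CODON_BASES)
    for k, c in enumerate(_CODON_BASES)
}


def single_step_missense_pairs() -> dict[tuple[str, str], int]:
    """Missense (ref_aa, alt_aa) pairs reachable by one nucleotide change,
    with codon-path multiplicities."""
    pairs: dict[tuple[str, str], int] = {}
    for codon, aa in GENETIC_CODE.items():
        if aa == STOP:
            continue
        for i in range(3):
            for b in "ACGT":
                if b == codon[i]:
                    continue
                alt = GENETIC_CODE[codon[:i] + b + codon[i + 1:]]
                if alt == STOP or alt == aa:
                    continue
                pairs[(aa, alt)] = pairs.get((aa, alt), 0) + 1
    return pairs


@dataclass(slots=True)
class TiltedSubstitutionTable:
    """Missense-pair distribution with expected KD shift == ``target_bias``."""

    pairs: list[tuple[str, str]]
    probs: np.ndarray
    deltas: np.ndarray
    beta: float
    target_bias: float

    def mean_delta(self) -> float:
        return float(self.probs @ self.deltas)


def tilted_substitution_table(hydro_bias: float) -> TiltedSubstitutionTable:
    """Exponentially tilt the single-step missense table so that the mean
    Kyte-Doolittle shift equals ``hydro_bias``.

    Weights are ``count * exp(beta * delta)``; beta is solved by root
    finding. Biases at or beyond the extreme achievable shift (about
    +/- 9 KD units) are infeasible and raise ``ValueError``.
    """
    base = single_step_missense_pairs()
    pairs = sorted(base)
    counts = np.array([base[p] for p in pairs], dtype=float)
    deltas = np.array([KD_SCALE[b] - KD_SCALE[a] for a, b in pairs])

    lo, hi = deltas.min(), deltas.max()
    if not (lo < hydro_bias < hi):
        raise ValueError(
            f"hydro_bias {hydro_bias} outside the achievable KD-shift range "
            f"({lo:.1f}, {hi:.1f})")

    def mean_at(beta: float) -> float:
        w = counts * np.exp(beta * (deltas - deltas.mean()))
        w /= w.sum()
        return float(w @ deltas) - hydro_bias

    b_lo, b_hi = -1.0, 1.0
    while mean_at(b_lo) > 0:
        b_lo *= 2
        if b_lo < -700:
            raise ValueError("hydro_bias numerically unreachable")
    while mean_at(b_hi) < 0:
        b_hi *= 2
        if b_hi > 700:
            raise ValueError("hydro_bias numerically unreachable")
    beta = brentq(mean_at, b_lo, b_hi, xtol=1e-12)
    w = counts * np.exp(beta * (deltas - deltas.mean()))
    probs = w / w.sum()
    return TiltedSubstitutionTable(pairs=list(pairs), probs=probs,
                                   deltas=deltas, beta=float(beta),
                                   target_bias=hydro_bias)


# ---------------------------------------------------------------------------
# Cohort specification

@dataclass(slots=True)
class GroupSpec:
    """One anatomical site group: sample count, burden log-normal
    (median in mutations, sigma on the log scale) and etiology mixture."""

    n_samples: int
    burden_median: float
    burden_sigma: float
    mixture: dict[str, float]  # signature name -> weight, sums to 1
    n_paired_patients: int = 0  # patients contributing two samples


def _default_groups() -> dict[str, GroupSpec]:
    # Expected group means: median * exp(sigma^2 / 2) ~= 925 (face/scalp)
    # and ~= 63 (other/visceral), so the expected cohort mean is
    # (11*925 + 37*63)/48 ~= 260 mutations/sample.
    return {
        "face_scalp": GroupSpec(11, 450.0, 1.2,
                                {"UV": 0.75, "AGING": 0.25}, 3),
        "other": GroupSpec(33, 40.0, 0.95,
                           {"AGING": 0.85, "UV": 0.05, "MMR": 0.10}, 8),
        "visceral": GroupSpec(4, 40.0, 0.95,
                              {"MMR": 0.60, "AGING": 0.40}, 1),
    }


@dataclass(slots=True)
class CohortSpec:
    """Study-condition parameters for cohort simulation."""

    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    burden_min: int = 8
    consequence_probs: dict[str, float] = field(default_factory=lambda: {
        "missense": 0.61, "silent": 0.31, "nonsense": 0.03,
        "splice": 0.03, "other": 0.02,
    })
    hydro_bias: float = 0.9240
    capture_size_bp: int = 30_000_000
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return sum(g.n_samples for g in self.groups.values())

    def validate(self) -> None:
        if abs(sum(self.consequence_probs.values()) - 1.0) > 1e-9:
            raise ValueError("consequence_probs must sum to 1")
        for name, g in self.groups.items():
            if abs(sum(g.mixture.values()) - 1.0) > 1e-9:
                raise ValueError(f"group {name!r}: mixture must sum to 1")
            if 2 * g.n_paired_patients > g.n_samples:
                raise ValueError(f"group {name!r}: too many paired patients")


# ---------------------------------------------------------------------------
# Simulation

def _draw_burden(rng: np.random.Generator, g: GroupSpec, minimum: int) -> int:
    n = int(round(rng.lognormal(mean=math.log(g.burden_median),
                                sigma=g.burden_sigma)))
    return max(n, minimum)


def simulate_cohort(spec: CohortSpec | None = None,
                    matrix: SignatureMatrix | None = None,
                    seed: int | None = None,
                    ) -> tuple[list[VariantRecord], list[SampleMeta], dict]:
    """Simulate a cohort; deterministic given the seed.

    Returns ``(variants, meta, ground_truth)``. ``ground_truth`` records
    the signature matrix name list, every sample's group, burden and
    mixture, and per-variant latent draws (signature, channel, strand
    flip, consequence), sufficient to audit each generated variant.
    """
    spec = spec or CohortSpec()
    spec.validate()
    matrix = matrix or synthetic_signature_matrix()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    subst = tilted_substitution_table(spec.hydro_bias)
    csq_classes = list(spec.consequence_probs)
    csq_probs = np.array([spec.consequence_probs[c] for c in csq_classes])
    aas = sorted(KD_SCALE)
    sig_index = {n: j for j, n in enumerate(matrix.names)}

    variants: list[VariantRecord] = []
    meta: list[SampleMeta] = []
    truth: dict = {
        "seed": int(spec.seed if seed is None else seed),
        "signatures": list(matrix.names),
        "hydro_bias": spec.hydro_bias,
        "samples": {},
        "variants": {"sample": [], "signature": [], "channel": [],
                     "purine_strand": [], "consequence": []},
    }

    patient_counter = 0
    sample_counter = 0
    for group_name, g in spec.groups.items():
        unknown = set(g.mixture) - set(matrix.names)
        if unknown:
            raise ValueError(f"group {group_name!r} mixes unknown signatures "
                             f"{sorted(unknown)}")
        # patient assignment: first n_paired_patients contribute 2 samples
        patient_of_sample: list[str] = []
        for _ in range(g.n_paired_patients):
            patient_counter += 1
            patient_of_sample += [f"P{patient_counter:03d}"] * 2
        while len(patient_of_sample) < g.n_samples:
            patient_counter += 1
            patient_of_sample.append(f"P{patient_counter:03d}")

        mix = np.zeros(matrix.k)
        for name, wgt in g.mixture.items():
            mix[sig_index[name]] = wgt

        for patient_id in patient_of_sample:
            sample_counter += 1
            sid = f"S{sample_counter:03d}"
            meta.append(SampleMeta(sid, patient_id, group_name,
                                   spec.capture_size_bp))
            burden = _draw_burden(rng, g, spec.burden_min)
            truth["samples"][sid] = {
                "group": group_name, "burden": int(burden),
                "mixture": dict(g.mixture),
            }
            sigs = rng.choice(matrix.k, size=burden, p=mix)
            csqs = rng.choice(len(csq_classes), size=burden, p=csq_probs)
            flips = rng.random(burden) < 0.5
            for sig_j, csq_i, flip in zip(sigs, csqs, flips):
                channel = int(rng.choice(96, p=matrix.weights[:, sig_j]))
                label = CHANNELS_96[channel]
                five, sub, three = label[0], label[2:5], label[6]
                ref, alt = sub[0], sub[2]
                context = five + ref + three
                if flip:  # emit on the purine strand
                    context = reverse_complement(context)
                    ref = context[1]
                    alt = reverse_complement(alt)
                csq = csq_classes[csq_i]
                ref_aa = alt_aa = None
                aa_pos = None
                if csq == "missense":
                    pair_i = int(rng.choice(len(subst.pairs), p=subst.probs))
                    ref_aa, alt_aa = subst.pairs[pair_i]
                    aa_pos = int(rng.integers(1, 1000))
                elif csq == "silent":
                    ref_aa = alt_aa = aas[int(rng.integers(len(aas)))]
                    aa_pos = int(rng.integers(1, 1000))
                elif csq == "nonsense":
                    ref_aa = aas[int(rng.integers(len(aas)))]
                    alt_aa = STOP
                    aa_pos = int(rng.integers(1, 1000))
                variants.append(VariantRecord(
                    sample_id=sid,
                    chrom=f"chr{int(rng.integers(1, 23))}",
                    pos=int(rng.integers(1, 200_000_000)),
                    ref=ref, alt=alt, context=context,
                    consequence=csq, ref_aa=ref_aa, alt_aa=alt_aa,
                    aa_pos=aa_pos,
                ))
                truth["variants"]["sample"].append(sid)
                truth["variants"]["signature"].append(matrix.names[sig_j])
                truth["variants"]["channel"].append(label)
                truth["variants"]["purine_strand"].append(bool(flip))
                truth["variants"]["consequence"].append(csq)

    return variants, meta, truth
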