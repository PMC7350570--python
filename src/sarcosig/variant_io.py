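"""Cohort variant-table and sample-metadata I/O.

The canonical on-disk form is a UTF-8, tab-separated table with LF line
endings and one row per somatic variant. Coordinates are 1-based, fully
closed (MAF convention). Two header dialects are supported:

``generic_tsv``
    columns ``sample  chrom  pos  ref  alt  context  consequence
    protein_change`` (the last three optional);
``maf_like``
    MAF-style headers (``Tumor_Sample_Barcode``, ``Chromosome``,
    ``Start_Position``, ``Reference_Allele``, ``Tumor_Seq_Allele2``,
    ``CONTEXT``, ``Variant_Classification``, ``HGVSp_Short``).

A custom column mapping (e.g. loaded from a YAML config) can override
either dialect. Rows that violate the record invariants are rejected with
a logged reason and counted; rejection never aborts the read. Alleles are
parsed case-insensitively and stored upper-case; ``-`` denotes the empty
allele of an insertion/deletion. Indels are retained (they count towards
mutation burden) but are excluded downstream from spectrum and
hydrophobicity computations, which operate on single-nucleotide
substitutions only.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

#: recognised consequence classes, in report order
CONSEQUENCE_CLASSES = ("missense", "silent", "nonsense", "splice", "other", "unknown")

#: marker stored in ``alt_aa`` for a stop-gain change
STOP = "*"

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class ConfigurationError(ValueError):
    """Raised when an input file or column mapping is structurally unusable."""


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One somatic variant.

    ``ref``/``alt`` are single upper-case nucleotides, or ``-`` for the
    empty side of an indel. ``context`` is the reference trinucleotide
    centred on the variant position (middle base equals ``ref``), when
    known. Protein-level fields are populated for coding substitutions
    with a parseable protein change; ``alt_aa == "*"`` marks a stop gain.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    context: str | None = None
    consequence: str = "unknown"
    ref_aa: str | None = None
    alt_aa: str | None = None
    aa_pos: int | None = None

    @property
    def is_snv(self) -> bool:
        return self.ref in NUCLEOTIDES and self.alt in NUCLEOTIDES

    @property
    def is_indel(self) -> bool:
        return self.ref == "-" or self.alt == "-"


@dataclass(frozen=True, slots=True)
class SampleMeta:
    """Sample-level metadata: patient mapping, anatomical site group and
    the WES capture size used as the TMB denominator."""

    sample_id: str
    patient_id: str
    site_group: str
    capture_size_bp: int


SITE_GROUPS = ("face_scalp", "other", "visceral")


@dataclass(slots=True)
class ReadResult:
    """Outcome of reading a variant table: accepted records plus an audit
    trail of rejected rows and raw consequence strings."""

    records: list[VariantRecord] = field(default_factory=list)
    rejected: list[tuple[int, str]] = field(default_factory=list)
    raw_consequences: Counter = field(default_factory=Counter)
    n_context_dropped: int = 0

    @property
    def n_accepted(self) -> int:
        return len(self.records)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


# ---------------------------------------------------------------------------
# HGVS protein-change parsing

_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": STOP,
}

_HGVS1 = re.compile(r"^([A-Z])(\d+)([A-Z*=])$")
_HGVS3 = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|\*|=)$")


def parse_hgvs_p(text: str) -> tuple[str, int, str] | None:
    """Parse a simple HGVS protein substitution into ``(ref_aa, pos, alt_aa)``.

    Accepts ``p.A123V``, ``A123V``, ``p.Ala123Val``, silent forms
    ``p.A123=`` / ``p.A123A`` and stop gains ``p.Q61*`` / ``p.Gln61Ter``.
    Frameshift, extension, indel and any other notation returns ``None``
    ("not parseable").
    """
    if not text:
        return None
    s = text.strip()
    if s.startswith("p."):
        s = s[2:]
    if s.startswith("(") and s.endswith(")"):
        s = s[1:-1]
    m = _HGVS1.match(s)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if ref not in STANDARD_AA:
            return None
        if alt == "=":
            alt = ref
        if alt not in STANDARD_AA and alt != STOP:
            return None
        return ref, pos, alt
    m = _HGVS3.match(s)
    if m:
        ref3, pos, alt3 = m.group(1), int(m.group(2)), m.group(3)
        if ref3 not in _AA3TO1 or ref3 == "Ter":
            return None
        ref = _AA3TO1[ref3]
        if alt3 == "=":
            alt = ref
        elif alt3 == "*":
            alt = STOP
        elif alt3 in _AA3TO1:
            alt = _AA3TO1[alt3]
        else:
            return None
        return ref, pos, alt
    return None


def format_hgvs_p(record: VariantRecord) -> str:
    """Canonical protein-change string for writing; empty if no aa info."""
    if record.ref_aa is None or record.aa_pos is None or record.alt_aa is None:
        return ""
    if record.alt_aa == STOP:
        return f"p.{record.ref_aa}{record.aa_pos}*"
    if record.alt_aa == record.ref_aa:
        return f"p.{record.ref_aa}{record.aa_pos}="
    return f"p.{record.ref_aa}{record.aa_pos}{record.alt_aa}"


# ---------------------------------------------------------------------------
# Dialects

#: logical field -> header name, per dialect
DIALECTS: dict[str, dict[str, str]] = {
    "generic_tsv": {
        "sample": "sample", "chrom": "chrom", "pos": "pos",
        "ref": "ref", "alt": "alt", "context": "context",
        "consequence": "consequence", "protein_change": "protein_change",
    },
    "maf_like": {
        "sample": "Tumor_Sample_Barcode", "chrom": "Chromosome",
        "pos": "Start_Position", "ref": "Reference_Allele",
        "alt": "Tumor_Seq_Allele2", "context": "CONTEXT",
        "consequence": "Variant_Classification", "protein_change": "HGVSp_Short",
    },
}

_MANDATORY = ("sample", "chrom", "pos", "ref", "alt")

_CONSEQUENCE_ALIASES = {
    "missense": "missense", "missense_mutation": "missense",
    "missense_variant": "missense",
    "silent": "silent", "synonymous": "silent", "synonymous_variant": "silent",
    "nonsense": "nonsense", "nonsense_mutation": "nonsense",
    "stop_gained": "nonsense",
    "splice": "splice", "splice_site": "splice", "splice_region": "splice",
    "splice_region_variant": "splice",
    "": "unknown", "na": "unknown", "nan": "unknown", "unknown": "unknown",
    ".": "unknown",
}


def normalize_consequence(raw: str | None) -> str:
    """Map a raw annotation string onto the internal consequence classes.

    Unrecognised strings map to ``other`` (never silently to missense);
    missing values map to ``unknown``.
    """
    if raw is None:
        return "unknown"
    key = str(raw).strip().lower()
    return _CONSEQUENCE_ALIASES.get(key, "other")


def load_column_map(path) -> dict[str, str]:
    """Load a YAML column mapping (logical field -> header name)."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    unknown = set(mapping) - set(DIALECTS["generic_tsv"])
    if unknown:
        raise ConfigurationError(f"unknown column-map keys: {sorted(unknown)}")
    return {str(k): str(v) for k, v in mapping.items()}


# ---------------------------------------------------------------------------
# Row validation

def _clean_allele(raw) -> str | None:
    s = str(raw).strip().upper()
    if s == "-":
        return s
    if len(s) == 1 and s in NUCLEOTIDES:
        return s
    return None


def validate_record(rec: VariantRecord) -> str | None:
    """Return a rejection reason, or ``None`` if the record is valid."""
    if rec.is_snv and rec.ref == rec.alt:
        return "ref equals alt"
    if not rec.is_snv and not rec.is_indel:
        return "unparseable allele"
    if rec.context is not None:
        if len(rec.context) != 3 or any(b not in NUCLEOTIDES for b in rec.context):
            return "malformed context"
        if rec.context[1] != rec.ref:
            return "context middle base does not match ref"
    if rec.consequence == "missense":
        if rec.ref_aa is None or rec.alt_aa is None:
            return "missense without amino-acid change"
        if rec.ref_aa == rec.alt_aa:
            return "missense with identical amino acids"
    if rec.consequence == "silent":
        if rec.ref_aa is not None and rec.alt_aa is not None and rec.ref_aa != rec.alt_aa:
            return "silent with differing amino acids"
    return None


def _row_to_record(row: dict, colmap: dict[str, str]) -> tuple[VariantRecord | None, str | None]:
    def get(field):
        col = colmap.get(field)
        if col is None or col not in row:
            return None
        v = row[col]
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return None
        s = str(v).strip()
        return s if s else None

    ref = _clean_allele(row[colmap["ref"]])
    alt = _clean_allele(row[colmap["alt"]])
    if ref is None or alt is None:
        return None, "unparseable allele"
    try:
        pos = int(row[colmap["pos"]])
    except (TypeError, ValueError):
        return None, "unparseable position"

    context = get("context")
    if context is not None:
        context = context.upper()

    raw_csq = get("consequence")
    consequence = normalize_consequence(raw_csq)

    ref_aa = alt_aa = None
    aa_pos = None
    pchange = get("protein_change")
    if pchange:
        parsed = parse_hgvs_p(pchange)
        if parsed is not None:
            ref_aa, aa_pos, alt_aa = parsed
        elif consequence in ("missense", "silent"):
            # frameshift/extension etc. annotated as a substitution class:
            # keep the row but demote to `other` so invariants hold
            consequence = "other"
    if consequence == "unknown" and ref_aa is not None:
        if alt_aa == STOP:
            consequence = "nonsense"
        elif alt_aa == ref_aa:
            consequence = "silent"
        else:
            consequence = "missense"
    if consequence == "nonsense" and ref_aa is not None and alt_aa != STOP:
        alt_aa = STOP

    rec = VariantRecord(
        sample_id=str(row[colmap["sample"]]).strip(),
        chrom=str(row[colmap["chrom"]]).strip(),
        pos=pos, ref=ref, alt=alt, context=context,
        consequence=consequence, ref_aa=ref_aa, alt_aa=alt_aa, aa_pos=aa_pos,
    )
    return rec, validate_record(rec)


def read_variant_table(path, dialect: str = "generic_tsv",
                       column_map: dict[str, str] | None = None) -> ReadResult:
    """Read a cohort variant table.

    Returns a :class:`ReadResult` whose ``records`` preserve file order.
    Rows failing the record invariants are rejected (logged, counted),
    not fatal; a missing mandatory column is a :class:`ConfigurationError`.
    A malformed trinucleotide context drops the context, not the row.
    """
    if dialect not in DIALECTS:
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    colmap = dict(DIALECTS[dialect])
    if column_map:
        colmap.update(column_map)

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for field_ in _MANDATORY:
        if colmap[field_] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {colmap[field_]!r} (field {field_!r}) "
                f"missing from {path}")

    result = ReadResult()
    for i, row in enumerate(df.to_dict("records")):
        csq_col = colmap.get("consequence")
        if csq_col in df.columns:
            result.raw_consequences[str(row[csq_col]).strip()] += 1
        rec, reason = _row_to_record(row, colmap)
        if reason == "context middle base does not match ref" or reason == "malformed context":
            # salvage the row without its context
            rec = VariantRecord(
                sample_id=rec.sample_id, chrom=rec.chrom, pos=rec.pos,
                ref=rec.ref, alt=rec.alt, context=None,
                consequence=rec.consequence, ref_aa=rec.ref_aa,
                alt_aa=rec.alt_aa, aa_pos=rec.aa_pos)
            result.n_context_dropped += 1
            reason = validate_record(rec)
        if reason is not None:
            logger.info("rejected row %d: %s", i + 2, reason)
            result.rejected.append((i + 2, reason))  # 1-based incl. header
        else:
            result.records.append(rec)
    logger.info("read %d records, rejected %d rows from %s",
                result.n_accepted, result.n_rejected, path)
    return result


_CANONICAL_COLUMNS = ("sample", "chrom", "pos", "ref", "alt",
                      "context", "consequence", "protein_change")


def write_variant_table(records, path) -> None:
    """Write records in the canonical ``generic_tsv`` dialect (fixed column
    order, UTF-8, LF line endings)."""
    rows = [{
        "sample": r.sample_id, "chrom": r.chrom, "pos": r.pos,
        "ref": r.ref, "alt": r.alt,
        "context": r.context or "",
        "consequence": r.consequence,
        "protein_change": format_hgvs_p(r),
    } for r in records]
    df = pd.DataFrame(rows, columns=list(_CANONICAL_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Sample metadata

def read_sample_meta(path) -> list[SampleMeta]:
    """Read the sample metadata table (sample_id, patient_id, site_group,
    capture_size_bp). Duplicate sample ids or invalid fields abort."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("sample_id", "patient_id", "site_group", "capture_size_bp")
    for col in required:
        if col not in df.columns:
            raise ConfigurationError(f"mandatory column {col!r} missing from {path}")
    metas = []
    seen = set()
    for row in df.to_dict("records"):
        sid = str(row["sample_id"]).strip()
        if sid in seen:
            raise ConfigurationError(f"duplicate sample_id {sid!r}")
        seen.add(sid)
        group = str(row["site_group"]).strip()
        if group not in SITE_GROUPS:
            raise ConfigurationError(
                f"sample {sid!r}: site_group {group!r} not in {SITE_GROUPS}")
        size = int(row["capture_size_bp"])
        if size <= 0:
            raise ConfigurationError(f"sample {sid!r}: capture_size_bp must be > 0")
        metas.append(SampleMeta(sid, str(row["patient_id"]).strip(), group, size))
    return metas


def write_sample_meta(metas, path) -> None:
    df = pd.DataFrame([{
        "sample_id": m.sample_id, "patient_id": m.patient_id,
        "site_group": m.site_group, "capture_size_bp": m.capture_size_bp,
    } for m in metas], columns=["sample_id", "patient_id", "site_group",
                                "capture_size_bp"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
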