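"""End-to-end analysis orchestration.

Runs burden -> spectra -> consequences -> hydrophobicity -> signatures on
a variant table plus sample metadata and writes one TSV/JSON artifact per
stage, together with a JSON manifest recording package version, seed,
input checksums, per-stage row accounting and every threshold used. All
stages are deterministic, so re-running on identical inputs reproduces
every output bit-for-bit (the manifest's checksums make this checkable).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .consequence import consequence_frame, ranked_aa_changes, tabulate_consequences
from .hydrophobicity import collect_deltas, cohort_shift
from .signatures import (etiology_summary, exposures_frame, fit_cohort,
                         load_etiology_map, read_signature_matrix)
from .spectrum import build_spectra, cohort_raw12, spectra_frame
from .tmb import compare_groups, compute_burden, group_counts
from .variant_io import read_sample_meta, read_variant_table

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class RunConfig:
    """Paths and options for a pipeline run."""

    variants: Path
    meta: Path
    out_dir: Path
    signature_matrix: Path | None = None
    etiology_map: Path | None = None
    dialect: str = "generic_tsv"
    min_exposure: float = 0.06
    min_snv: int = 50
    compare: list[tuple[str, str]] = field(
        default_factory=lambda: [("face_scalp", "rest")])
    test_method: str = "welch_t"
    seed: int = 0

    def validate(self) -> None:
        for p in (self.variants, self.meta, self.signature_matrix,
                  self.etiology_map):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # --- ingest -----------------------------------------------------------
    read = read_variant_table(config.variants, dialect=config.dialect)
    meta = read_sample_meta(config.meta)
    variants = read.records
    logger.info("stage ingest: %d accepted, %d rejected, %d contexts dropped",
                read.n_accepted, read.n_rejected, read.n_context_dropped)

    # --- burden -----------------------------------------------------------
    burden = compute_burden(variants, meta)
    path = out / "burden.tsv"
    burden.per_sample.to_csv(path, sep="\t", index=False, lineterminator="\n")
    outputs["burden"] = path

    comparisons = []
    for ga, gb in config.compare:
        a = group_counts(burden, ga)
        b = (group_counts(burden, ga, complement=True) if gb == "rest"
             else group_counts(burden, gb))
        if a and b:
            res = compare_groups(a, b, method=config.test_method,
                                 label_a=ga, label_b=gb)
            comparisons.append({
                f: getattr(res, f)
                for f in ("group_a", "group_b", "method", "statistic",
                          "p_value", "n_a", "n_b", "degenerate")})
    burden_summary = {
        "summary": burden.summary,
        "group_means": burden.group_means,
        "comparisons": comparisons,
    }
    path = out / "burden_summary.json"
    path.write_text(json.dumps(burden_summary, indent=2, sort_keys=True) + "\n")
    outputs["burden_summary"] = path

    # --- spectra ----------------------------------------------------------
    spectra = build_spectra(variants, samples=[m.sample_id for m in meta])
    path = out / "spectra.tsv"
    spectra_frame(spectra).to_csv(path, sep="\t", index=False,
                                  lineterminator="\n")
    outputs["spectra"] = path

    # --- consequences -----------------------------------------------------
    table = tabulate_consequences(variants)
    path = out / "consequence_counts.tsv"
    consequence_frame(table).to_csv(path, sep="\t", index=False,
                                    lineterminator="\n")
    outputs["consequence_counts"] = path
    path = out / "aa_changes.tsv"
    ranked_aa_changes(table).to_csv(path, sep="\t", index=False,
                                    lineterminator="\n")
    outputs["aa_changes"] = path

    # --- hydrophobicity ---------------------------------------------------
    deltas, n_excluded = collect_deltas(variants)
    hydro = None
    if deltas:
        report = cohort_shift(deltas)
        hydro = {
            "n": report.n, "n_increasing": report.n_increasing,
            "frac_increasing": report.frac_increasing,
            "mean_delta": report.mean_delta,
            "ci95_low": report.ci95[0], "ci95_high": report.ci95[1],
            "p_paired": report.p_paired, "t_statistic": report.t_statistic,
            "n_excluded_nonstandard": n_excluded,
        }
    path = out / "hydrophobicity.json"
    path.write_text(json.dumps(hydro, indent=2, sort_keys=True) + "\n")
    outputs["hydrophobicity"] = path

    # --- signatures -------------------------------------------------------
    if config.signature_matrix is not None:
        matrix = read_signature_matrix(config.signature_matrix)
        profiles = fit_cohort(spectra, matrix,
                              min_exposure=config.min_exposure,
                              min_snv=config.min_snv)
        path = out / "exposures.tsv"
        exposures_frame(profiles).to_csv(path, sep="\t", index=False,
                                         lineterminator="\n")
        outputs["exposures"] = path
        et_map = load_etiology_map(config.etiology_map)
        defined = [p for p in profiles if p.defined]
        path = out / "etiologies.tsv"
        etiology_summary(defined, et_map).to_csv(path, sep="\t", index=False,
                                                 lineterminator="\n")
        outputs["etiologies"] = path

    # --- manifest ---------------------------------------------------------
    manifest = {
        "package": "sarcosig",
        "version": __version__,
        "seed": config.seed,
        "options": {
            "dialect": config.dialect,
            "min_exposure": config.min_exposure,
            "min_snv": config.min_snv,
            "test_method": config.test_method,
        },
        "accounting": {
            "rows_accepted": read.n_accepted,
            "rows_rejected": read.n_rejected,
            "contexts_dropped": read.n_context_dropped,
            "cohort_raw12": cohort_raw12(spectra),
        },
        "inputs": {str(k): _sha256(Path(v)) for k, v in {
            "variants": config.variants, "meta": config.meta,
            **({"signature_matrix": config.signature_matrix}
               if config.signature_matrix else {}),
        }.items()},
        "outputs": {name: {"path": p.name, "sha256": _sha256(p)}
                    for name, p in outputs.items()},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d output files", len(outputs) + 1)
    return manifest
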