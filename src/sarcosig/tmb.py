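"""Per-sample mutation burden and group comparisons.

Tumor mutation burden (TMB) is the number of accepted variants in a
sample (substitutions and indels alike) divided by the sample's WES
capture size, expressed per megabase. Samples — not patients — are the
unit of analysis; an optional patient-collapsed mode averages each
patient's samples first, as a sensitivity analysis.

Group comparisons offer Welch's unequal-variance t test (default) and the
Mann-Whitney U test; exome burden is heavy-tailed, so the rank test is
often the safer choice. Both are two-sided. Mann-Whitney uses scipy's
default method selection (exact for small tie-free samples, otherwise the
tie-corrected normal approximation with continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import SampleMeta, VariantRecord

COMPARE_METHODS = ("welch_t", "mann_whitney")


@dataclass(slots=True)
class ComparisonResult:
    group_a: str
    group_b: str
    method: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    degenerate: bool = False  # e.g. Welch t with a singleton group


@dataclass(slots=True)
class BurdenTable:
    """Per-sample counts/TMB plus group means and cohort summary."""

    per_sample: pd.DataFrame   # sample_id, patient_id, site_group, n_mutations, tmb_per_mb
    group_means: dict[str, float]
    summary: dict[str, float]


def compute_burden(variants: list[VariantRecord], meta: list[SampleMeta],
                   per_patient: bool = False) -> BurdenTable:
    """Count mutations per sample and normalise by capture size.

    Every variant's sample must appear in ``meta`` (orphans abort with the
    offending sample named); metadata samples without variants get count 0.
    With ``per_patient`` the summary statistics are computed on
    patient-mean counts instead of samples.
    """
    by_sample = {m.sample_id: m for m in meta}
    counts = {m.sample_id: 0 for m in meta}
    for v in variants:
        if v.sample_id not in by_sample:
            raise KeyError(f"variant sample {v.sample_id!r} absent from metadata")
        counts[v.sample_id] += 1

    rows = [{
        "sample_id": m.sample_id,
        "patient_id": m.patient_id,
        "site_group": m.site_group,
        "n_mutations": counts[m.sample_id],
        "tmb_per_mb": counts[m.sample_id] / (m.capture_size_bp / 1e6),
    } for m in meta]
    df = pd.DataFrame(rows, columns=["sample_id", "patient_id", "site_group",
                                     "n_mutations", "tmb_per_mb"])

    unit = (df.groupby("patient_id")["n_mutations"].mean()
            if per_patient else df["n_mutations"])
    group_means = df.groupby("site_group")["n_mutations"].mean().to_dict()
    summary = {
        "n_samples": int(df.shape[0]),
        "n_patients": int(df["patient_id"].nunique()),
        "n_variants": int(df["n_mutations"].sum()),
        "mean_mutations": float(unit.mean()) if len(unit) else float("nan"),
        "min_mutations": int(unit.min()) if len(unit) else 0,
        "max_mutations": int(unit.max()) if len(unit) else 0,
        "unit": "patient" if per_patient else "sample",
    }
    return BurdenTable(per_sample=df, group_means=group_means, summary=summary)


def group_counts(table: BurdenTable, group: str,
                 complement: bool = False) -> list[int]:
    """Mutation counts of a site group (or of its complement)."""
    df = table.per_sample
    mask = df["site_group"] == group
    if complement:
        mask = ~mask
    return df.loc[mask, "n_mutations"].tolist()


def compare_groups(counts_a: list[int], counts_b: list[int],
                   method: str = "welch_t",
                   label_a: str = "a", label_b: str = "b") -> ComparisonResult:
    """Two-sided location comparison of two burden vectors.

    Symmetric up to the sign of the statistic (Welch t) or up to
    U <-> n_a*n_b - U (Mann-Whitney); p-values are unchanged under
    argument swap.
    """
    if not counts_a or not counts_b:
        raise ValueError("both groups must be non-empty")
    if method not in COMPARE_METHODS:
        raise ValueError(f"method must be one of {COMPARE_METHODS}")
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    degenerate = False
    if method == "welch_t":
        if len(a) < 2 or len(b) < 2:
            degenerate = True
            stat, p = float("nan"), float("nan")
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(group_a=label_a, group_b=label_b, method=method,
                            statistic=stat, p_value=p,
                            n_a=len(a), n_b=len(b), degenerate=degenerate)
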