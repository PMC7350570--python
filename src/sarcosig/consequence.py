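"""Protein-level consequence tabulation.

Counts variants by consequence class (missense, silent, nonsense, splice,
other, unknown — a partition of the input) and, over missense variants
only, tallies the (reference residue, alternate residue) change pairs.
The ranked change-pair report annotates each pair with the sign of its
Kyte-Doolittle hydropathy shift; ties in the ranking are broken by
descending count then lexicographic pair label, so reports are
deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .hydrophobicity import KD_SCALE, kd_delta
from .variant_io import CONSEQUENCE_CLASSES, VariantRecord


@dataclass(slots=True)
class ConsequenceTable:
    counts: dict[str, int]
    aa_changes: Counter = field(default_factory=Counter)
    n_total: int = 0

    def percentages(self) -> dict[str, int]:
        """Class percentages against the total variant count, to integer percent."""
        if self.n_total == 0:
            return {c: 0 for c in self.counts}
        return {c: round(100 * n / self.n_total) for c, n in self.counts.items()}


def tabulate_consequences(variants: list[VariantRecord]) -> ConsequenceTable:
    """Count consequence classes and missense amino-acid change pairs.

    Every variant lands in exactly one class; the change-pair total equals
    the missense count.
    """
    counts = {c: 0 for c in CONSEQUENCE_CLASSES}
    aa_changes: Counter = Counter()
    for v in variants:
        counts[v.consequence] += 1
        if v.consequence == "missense":
            aa_changes[(v.ref_aa, v.alt_aa)] += 1
    return ConsequenceTable(counts=counts, aa_changes=aa_changes,
                            n_total=len(variants))


def ranked_aa_changes(table: ConsequenceTable, top: int | None = None) -> pd.DataFrame:
    """Change pairs ranked by count (desc), ties by pair label.

    Columns: ref_aa, alt_aa, count, kd_delta, hydrophobicity_increasing.
    The hydropathy delta is NA for pairs involving non-standard residues.
    """
    items = sorted(table.aa_changes.items(),
                   key=lambda kv: (-kv[1], f"{kv[0][0]}>{kv[0][1]}"))
    if top is not None:
        items = items[:top]
    rows = []
    for (ref_aa, alt_aa), count in items:
        if ref_aa in KD_SCALE and alt_aa in KD_SCALE:
            delta = kd_delta(ref_aa, alt_aa)
            rows.append({"ref_aa": ref_aa, "alt_aa": alt_aa, "count": count,
                         "kd_delta": delta,
                         "hydrophobicity_increasing": delta > 0})
        else:
            rows.append({"ref_aa": ref_aa, "alt_aa": alt_aa, "count": count,
                         "kd_delta": float("nan"),
                         "hydrophobicity_increasing": pd.NA})
    return pd.DataFrame(rows, columns=["ref_aa", "alt_aa", "count", "kd_delta",
                                       "hydrophobicity_increasing"])


def consequence_frame(table: ConsequenceTable) -> pd.DataFrame:
    """Class counts and integer percentages, in canonical class order."""
    pct = table.percentages()
    return pd.DataFrame(
        [{"consequence": c, "count": table.counts[c], "percent": pct[c]}
         for c in CONSEQUENCE_CLASSES],
        columns=["consequence", "count", "percent"])
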