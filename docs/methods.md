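# Methods

`sarcosig` analyses a cohort of somatic variants from whole-exome
sequencing (WES) at four levels — mutation burden, substitution spectrum,
protein-level hydrophobicity shift, and mutational-signature etiology —
and ships a synthetic cohort generator so every stage is testable without
access to patient-level data. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
tests do and do not demonstrate.

## Unit of analysis

The record of analysis is a single somatic variant (sample, 1-based
closed coordinate, ref/alt allele, optional reference trinucleotide
context, consequence class, optional HGVS-p protein change). Samples —
not patients — are the unit of all cohort statistics, because multi-lesion
patients genuinely contribute multiple tumours; a patient-collapsed mode
(mean count per patient) is available as a sensitivity analysis and off by
default. Indels are retained for burden counting but excluded from
spectrum and hydrophobicity computations, which are defined on
single-nucleotide substitutions. Rows violating record invariants
(ref equals alt, unparseable alleles, missense without an amino-acid
change) are rejected with a logged reason and counted, never silently
dropped, so total accounting — accepted + rejected = input rows — is
auditable from the manifest.

## Tumor mutation burden

Per sample, `n_mutations` counts all accepted variants and
`tmb_per_mb = n_mutations / (capture_size_bp / 1e6)`. The capture size is
part of the sample metadata because capture designs differ between
cohorts; the default synthetic cohort uses 30 Mb, a typical exome target
territory. Group comparisons are two-sided and offered as Welch's
unequal-variance t test (default) or the Mann-Whitney U test; exome
burden is strongly heavy-tailed, so the rank test is usually the more
defensible choice and both methods are recorded in the output. Welch on a
singleton group is flagged degenerate rather than computed. On identical
constant groups Mann-Whitney returns p = 1.0 exactly (scipy's exact
method); with ties the tie-corrected normal approximation with continuity
correction is used.

## Substitution spectra

Each SNV is classified twice:

* into one of the 12 raw ordered classes (`A>C` … `T>G`), with no strand
  collapsing, so transition excesses visible on either strand (`G>A`
  versus `C>T`) are reported separately;
* into one of the 96 trinucleotide channels: the substitution collapsed
  onto the pyrimidine strand (6 types) crossed with the 5' and 3'
  flanking bases, labelled `A[C>T]G` style.

Channel order is fixed (substitution-major, then 5' base, then 3' base,
alphabetical) so spectrum files compare bit-for-bit. Contexts are taken
from the input table when present; variants without a usable context
still count in the 12 classes and their number is reported per sample,
avoiding any dependency on a reference-genome download. Collapsing is
exactly involution-consistent: reverse-complementing every input variant
leaves the 96-channel spectrum unchanged (tested exhaustively over all
192 substitution/context combinations).

## Hydrophobicity shift

Missense changes are scored with the Kyte-Doolittle (1982) hydropathy
scale (`data/kd_scale.tsv`, auditable and replaceable; I = +4.5 the most
hydrophobic, R = −4.5 the least), as
`delta = KD(alt_aa) − KD(ref_aa)`. Increased peptide hydrophobicity is
the package's immunogenicity proxy; no MHC-binding prediction is
attempted. The cohort statistic pools all scoreable missense variants
(the per-sample alternative is not implemented because the pooled framing
matches the per-variant sample sizes reported downstream): mean delta, a
t-distribution 95% CI of the mean, and the p-value of a paired t test of
alternate- versus reference-residue hydropathy. The paired test is
computed as the one-sample t of the deltas against zero — an algebraic
identity asserted numerically in the tests. Non-standard residues
(U, B, Z, X, stop) are excluded with a logged count; silent variants
contribute zero-deltas only on request. A single observation yields a
flagged, undefined CI.

## Signature refitting

A reference matrix of K signatures (96 channels, unit-sum columns —
COSMIC v2 layout, user-supplied TSV) is fitted per sample by nonnegative
least squares on the count-normalised spectrum. The fit is therefore
scale-invariant (doubling all counts changes nothing) and
label-invariant (permuting columns permutes exposures). Exposures are
normalised to sum to one, entries below `min_exposure` (default 0.06,
following the deconstructSigs convention) are zeroed and the remainder
renormalised; the result is reported as a per-signature "probability" in
[0, 1]. Reconstruction quality is the cosine similarity between observed
and reconstructed spectra. Samples with fewer than `min_snv` (default 50)
context-bearing SNVs are fitted anyway but flagged low-confidence, since
small cohorts legitimately contain samples with under ten mutations; an
all-zero spectrum yields a flagged undefined profile. Etiology
probabilities sum member-signature exposures under an editable YAML
annotation (shipped: the standard COSMIC v2 assignments — 1 aging,
7 UV, 6/15/20/26 MMR, 2/13 APOBEC, 10 POLE, 9 POLH, …), clipped to
[0, 1]. De novo signature extraction and bootstrap CIs on exposures are
out of scope.

## Synthetic cohort generator

The generator emulates the structure of a small, anatomically
heterogeneous WES sarcoma cohort. Defaults (all exposed on
`CohortSpec`):

* **Cohort structure** — 48 samples from 36 patients (twelve patients
  contribute two samples each): 11 face/scalp, 33 other, 4 visceral.
* **Burden** — per-group log-normals truncated below at 8 mutations.
  Face/scalp: median 450, σ = 1.2 (expected mean
  450·e^(1.2²/2) ≈ 925); other/visceral: median 40, σ = 0.95 (expected
  mean ≈ 63). The expected cohort mean is (11·925 + 37·63)/48 ≈ 260
  mutations/sample. At these group sizes a single realisation of the
  face/scalp mean is noisy (SE ≈ 500), which is why cohort-mean checks
  average over replicate cohorts.
* **Signatures** — a synthetic 5-signature reference with idealised
  etiology profiles (aging: C>T at NpCpG; UV: C>T at dipyrimidines;
  MMR: mixed C>T/T>C; APOBEC: C>T/C>G at TpCpW; POLE: C>A at TpCpT),
  each with a small uniform background so no channel has zero
  probability. Group mixtures: face/scalp 0.75 UV / 0.25 aging; other
  0.85 aging / 0.05 UV / 0.10 MMR; visceral 0.60 MMR / 0.40 aging. Each
  variant's channel is drawn from the sample's mixture and emitted on a
  uniformly random strand, so contexts come from the channel draw
  directly — no reference genome is involved.
* **Consequences** — missense 0.61, silent 0.31, nonsense 0.03,
  splice 0.03, other 0.02.
* **Hydrophobicity** — missense amino-acid pairs are drawn from the
  single-nucleotide-accessible substitution table of the standard
  genetic code (keeping pairs reachable by one SNV), exponentially
  tilted by `exp(β·delta)` with β solved so the expected KD shift equals
  `hydro_bias` (default +0.9240). The untilted table is exactly
  symmetric (codon paths are reversible), so zero bias means β = 0.
  Targets outside the achievable shift range (≈ ±9 KD units) raise an
  error.

Everything is deterministic given the seed, and the ground-truth record
stores every latent draw (per-sample group/burden/mixture; per-variant
signature, channel, strand, consequence), so each generated variant can
be audited.

**What the generator does not emulate:** positional structure (positions
are uniform, no gene model, no mutation hotspots), purity/clonality,
copy number, sequencing error, indels, inter-variant correlation within
a sample beyond the shared signature mixture, and real COSMIC signature
shapes (the synthetic profiles are sharper and better separated than
several real signatures). Passing tests therefore demonstrate that the
statistics and the refitting machinery are implemented correctly and are
well calibrated under the stated model — not that signature attribution
on real tumours reaches any particular accuracy, since real references
contain near-collinear columns (e.g. signatures 5 and 16) where NNLS
attribution is intrinsically unstable.

## Numerical and design choices

* NNLS is solved unconstrained in scale and renormalised, rather than
  solved on the simplex; the residual is therefore never worse than any
  simplex point (checked against exhaustive grid search on K = 3).
* Top-k amino-acid-change rankings break ties by descending count, then
  lexicographic pair label, making reports deterministic.
* The "6 of the top 10 changes increase hydrophobicity"-style statement
  is reported, not asserted at a fixed value, because top-10 composition
  depends on tie-breaking near the cut.
* Group-comparison p-values are reported with their method; no specific
  test is hard-asserted where the method behind a published p-value is
  unstated.
* External comparison cohorts enter only as user-supplied per-sample
  count vectors; the pipeline downloads nothing.
* The pipeline is a pure function of (inputs, options): manifests record
  input/output SHA-256 checksums and every threshold, and re-runs are
  bit-identical.
* Problem sizes used by the checks: default cohort ≈ 10–14 k variants
  across 48 samples; mixture recovery at 5 000 mutations; null
  calibration at 1 000 replicates of 500 deltas — sizes at which the
  targeted moments are estimable to the tolerances used while the whole
  suite runs in seconds.

## Known limitations

Signature "probabilities" are normalised NNLS exposures, not posterior
probabilities; they carry no uncertainty quantification. The hydropathy
shift treats all missense variants as exchangeable regardless of
expression or clonality. Consequence classes are taken from the input
annotation (or inferred from the protein change), never re-derived from
transcripts. VCF ingestion is a documented non-goal for v1; tables are
TSV in either the generic or MAF-like dialect.
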