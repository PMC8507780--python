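# Methods

## The measurement model

Two isogenic cell lines are compared in one MS run per replicate: the
parental line grown in light medium and its derivative in heavy
(Lys8/Arg10) medium, so every tryptic or HLA-eluted peptide that
contains at least one lysine or arginine exists as a light/heavy pair
and the heavy/light intensity ratio H/L quantifies relative abundance
(H/L < 1: reduced in the derivative).  Three layers are measured from
the same lysate: the HLA class I-presented peptidome, the whole-cell
proteome, and the class I interactome from affinity purification of
the HLA complex.

The package takes peptide- or protein-level intensity tables (long
format, one row per species × replicate) as input.  Everything
upstream — spectra, database search, FDR estimation — is out of scope;
identification FDRs and unique-peptide counts arrive as columns.

## Quantification

**Normalization.**  `normalize_channels` rescales the heavy channel per
replicate.  Two factor estimators are provided: total-intensity
(ΣL/ΣH over rows with both channels measured, the classical
total-peptide normalization) and median-ratio centering
(1/median(H/L), MaxQuant-style).  The pipeline uses median centering
computed on the *whole-proteome* table and applies those factors to
every table of the run.  Rationale: a per-table sum or median
projection forces the table's own center to 1 and would erase a
genuine global shift of the peptidome, which is precisely the
biological signal of interest; the proteome bulk is unchanged between
the lines, so factors derived there estimate the technical channel
imbalance only.  Sum-based factors are additionally biased by the
heavy-tailed linear-scale means of strongly differential species
(Jensen's inequality), which is why the median is preferred for the
cross-table factors.

**Ratios and capping.**  Rows with both channels give H/L directly;
rows detected in only one channel receive the conventional capped
ratios 256 (heavy-only) and 0.01 (light-only).  These caps are also
the extremes of the representable ratio scale, so a (rare) measured
ratio outside [0.01, 256] is clipped; the `capped` flag records
one-channel detection only.  Rows with neither channel are
identification-only and are marked not-quantified rather than
erroring — they are exactly what the discovery cascade's
"quantified" stage removes.

**Aggregation.**  The summary log2 ratio per species is the median of
the uncapped replicate log2 ratios (robust to a single outlier or
capped replicate); capped values are conventions, not measurements,
and are excluded from the median and from significance testing.  A
species whose quantified replicates are all capped on the same side
keeps the capped summary; mixed heavy-only/light-only with no measured
replicate is uninterpretable and resolved by majority (ties dropped).
Significance is a two-sided one-sample t-test of the replicate log2
ratios against 0, computed when ≥ 2 uncapped replicates with nonzero
variance exist.

## Peptidome analysis

The discovery cascade counts peptides surviving: identification → at
least one K/R (only these can carry the heavy label) → a valid
(possibly capped) SILAC ratio → canonical class I length 8–14.
Differential presentation uses inclusive fold-change cutoffs
(ratio ≥ 2.0 increased, ≤ 0.5 reduced) with no significance
requirement, and capped peptides participate — a heavy-only peptide is
an increased call, which is what the capping convention exists for.
Summary percentages are integers rounded half away from zero; this
rounding reproduces every ratio-of-counts percentage the package
reports.  The global shift is the five-number summary of all log2
ratios, capped included.

## Binder calling

A position weight matrix per allele and length stands in for neural
binding-affinity predictors.  Training:
`freq[a][p] = (count(a,p) + pc·bg[a]) / (n + pc)` with pseudocount
pc = 1 weighted by the background residue distribution.  Scoring is
summed log2 odds against the background.  The %rank of a query is the
percentage of random reference-proteome windows (same length,
deduplicated, 2000 sampled with a recorded seed) scoring *strictly*
above it — the strict convention makes tie behavior exact and
testable.  Class thresholds follow field convention: strong ≤ 2.0,
weak ≤ 10.0.  The PWM stand-in claims pipeline logic, not
affinity-prediction accuracy; precomputed %rank columns from an
external predictor can be substituted at the CLI boundary.

Motif comparison between two equal-length peptide sets uses the
per-position, per-residue z-score
`z = (f_sample − f_ref) / sqrt(f_ref(1 − f_ref)/n_sample)`, with f_ref
floored at 1/(n_ref + 20) in the denominator only, so identical sets
give exactly z = 0 everywhere.

## Interactome analysis

High-confidence interactions (HCIs) pass identification FDR < 0.01
(strict), unique peptides ≥ 2 (inclusive), and absence from a
CRAPome-style contaminant list (accession match, optional gene-symbol
fallback for gene-keyed lists).  Replicate rows are collapsed to best
evidence (max unique peptides, min FDR) before filtering, making the
filter idempotent and order-independent.  Differential interaction
calls at 1.5/0.67 additionally require t-test p < 0.05 for measured
ratios; capped HCIs (one-channel) are called on the ratio alone since
no test is possible.  α = 0.05 is a package choice.  Overlap
statistics use inclusion–exclusion (union = |A| + |B| − |A∩B|), and
known-interactor recovery reports |known ∩ HCI| / |known| plus the
novel count |HCI| − |known ∩ HCI|.

## Integration

Peptide–protein correlation pairs each protein's median presented-
peptide log2 ratio with its expression log2 ratio (capped excluded
from both layers) and reports the least-squares slope, Pearson r and
two-sided p.  Proteome–interactome correlation is a plain Pearson test
on shared accessions.  Altered proteins are |log2 H/L| > 0.6 (strict).
Gene-set over-representation is the upper-tail hypergeometric
probability with Benjamini–Hochberg adjustment across sets; the
universe is all genes quantified in the relevant layer, standard
over-representation practice.  The per-pathway activation z-score is
sign concordance over the m altered genes with annotated expected
directions, `z = Σ sign(log2)·dir / √m`, bounded by ±√m — a
transparent stand-in for proprietary knowledge-base z-scores, not a
claim of equivalence to them.

## The synthetic generator

The generator defines the study conditions under which the pipeline is
validated; its defaults are fixed once, not tuned per run.

* **Peptides** are sampled from two synthetic allele PWMs with
  hydrophobic anchors at position 2 and the C-terminus (primary anchor
  residue frequency 0.55–0.60, K/R at 0.003 — anchor positions deplete
  the labelable residues, as real class I motifs do) and moderately
  informative non-anchor positions (0.60·background + 0.40 on a
  preferred residue).  The non-anchor information level was calibrated
  once so that motif-sampled binders are called strong with ≥ 0.85
  sensitivity by a PWM retrained on 200 sampled epitopes.
* **Lengths** default to a 9-mer-dominant distribution (43% 9-mers,
  93% within 8–14, a 7% tail at 15–16 so the cascade's length stage
  does real work).  The K/R-containing fraction defaults to 0.65.
* **Mapping.**  Each peptide is spliced into its source protein of a
  synthetic ~250-residue, background-frequency reference proteome
  (default 5000 proteins), so peptide→protein assignment is verifiable
  by substring search.
* **Planted effects.**  Of the quantifiable peptides, 54% default
  reduced (true log2 = −1.3 − Exp(0.8)), 5% increased (mirror image),
  the rest unchanged (N(global_log2_shift = −0.5, 0.2), clipped to
  ±0.75).  The differential groups sit beyond the ±1 cutoffs with a
  0.3 log2 margin and the unchanged bulk inside them with a 0.25
  margin: planted labels remain identifiable under replicate noise,
  where real data are continuous across the cutoff.  One-channel
  detections (2% heavy-only, 2% light-only) are carved out of the
  increased/reduced groups first so observed call fractions match the
  configured fractions.  A further 33% of labelable peptides are
  identification-only (no MS1 intensities), matching the attrition
  between the cascade's labelable and quantified stages.
* **Intensities** are log-normal: light = 2^(base + ε_rep), heavy =
  light · 2^(true log2 + ε), with replicate ratio noise
  noise_sd = 0.2 — chosen so replicate log2 ratios correlate at
  r > 0.95, comfortably above the r > 0.8 reproducibility bar.  All
  tables share one per-replicate technical channel-imbalance factor
  (log2 sd 0.1) that proteome-anchored normalization removes.
* **Interactome** tables contain 10% contaminant rows (drawn from a
  generated CRAPome-style list), 10% high-FDR and 10% single-peptide
  rows; the remaining HCIs carry 10% increased / 10% decreased planted
  interactions (|log2| ∈ [0.9, 2.2]) aligned with differentially
  expressed proteins, plus a 0.6-coupled bulk — this produces the
  planted positive proteome–interactome correlation, while peptide
  ratios are drawn independently of protein ratios (no
  peptidome–proteome correlation).  The known-interactor list is
  constructed for 40% recovery; gene sets include three planted
  activated and three inhibited pathways with direction annotations.

What the generator does **not** emulate: spectra, retention time,
charge states, isotope envelopes, fractionation, shared/razor-peptide
ambiguity, intensity-dependent missingness, or a continuum of effect
sizes across the decision cutoffs.  Passing tests therefore
demonstrate correctness of the pipeline's logic and statistics under a
clean planted-truth model, not robustness to every artifact of real
MS data.

## Numerical choices and degenerate inputs

Integer percentages round half away from zero.  %rank ties resolve by
the strictly-greater convention.  PWM columns must sum to 1 within
1e-9; backgrounds likewise.  Empty peptide lists, empty universes,
zero denominators, all-absent channels and sub-3-pair correlations
raise ValueError with the offending replicate or count named; a
peptide quantified in zero replicates is dropped, not an error.
Determinism: every random draw flows from one numpy Generator seeded
by the config, so identical configs give byte-identical fixture files;
%rank backgrounds record their seed.

## Problem sizes

The test suite runs one shared experiment (1200 peptides, 1200
proteins, 400 interactors, 3 replicates) through the full pipeline
plus many micro-fixtures; the acceptance script generates two pairs at
1217 and 867 peptides with 5000-protein proteomes.  These sizes give
binomial sampling error well inside the ±3–4 point recovery
tolerances while keeping a full run in tens of seconds.

## Known limitations

Capped ratios enter differential calls but not significance tests, so
a one-channel species can be called altered from a single replicate.
The hypergeometric universe ignores gene-set genes never quantified.
The activation z-score treats genes as independent and weights them
equally.  PWM scoring assumes positional independence — no pairwise
residue coupling.  The HCI filter's best-evidence replicate collapse
can admit a protein seen well in only one replicate.
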