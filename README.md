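# hlaquant

Quantitative SILAC analysis of the HLA class I immunopeptidome, the
whole-cell proteome and the class I interactome, for studying antigen
presentation changes between paired cell lines — e.g., an
osimertinib-sensitive EGFR-mutant lung adenocarcinoma line (light
labeled) against its acquired-resistance derivative (heavy labeled,
Lys8/Arg10).

In this design every species carries a heavy/light intensity ratio
H/L, with H/L < 1 meaning reduced abundance upon resistance.  The
package implements the full informatic pipeline downstream of the
database search:

* **Quantification** — per-replicate channel normalization, H/L ratios
  with the capping convention (256 for heavy-only, 0.01 for light-only
  detections), median aggregation over replicates, and a one-sample
  t-test of the replicate log2 ratios against 0.
* **Peptidome profiling** — the discovery cascade (identified → ≥1
  Lys/Arg, hence SILAC-labelable → valid ratio → canonical 8–14-mer
  length), length and Lys/Arg label-position distributions,
  differential presentation calls at the 2.0/0.5 fold-change cutoffs,
  and the global-shift (median log2 H/L) summary.
* **Binder calling** — a position-weight-matrix stand-in for neural
  binding predictors: per-allele PWMs trained on known epitopes
  (`freq = (count + pc·bg)/(n + pc)`), log-odds scoring
  `score = Σ_p log2(f_p(a)/bg(a))`, percentile rank against random
  reference-proteome windows (strong binder at %rank ≤ 2.0), and an
  iceLogo-style per-position residue z-score for motif comparison.
* **Interactome** — high-confidence interaction (HCI) filtering
  (identification FDR < 0.01, ≥ 2 unique peptides, not a CRAPome-style
  contaminant), Venn overlap and known-interactor recovery statistics,
  and differential interaction calls at 1.5/0.67 with a significance
  requirement.
* **Integration** — peptide-vs-source-protein and
  proteome-vs-interactome correlations, altered-protein selection at
  |log2 H/L| > 0.6, hypergeometric gene-set over-representation with
  Benjamini–Hochberg adjustment, and a sign-concordance activation
  z-score `z = Σ_g sign(log2_g)·dir_g / √m` per pathway.
* **Synthetic data** — a generator that emulates the whole experiment
  (anchor-constrained peptides spliced into a synthetic reference
  proteome, log-normal intensities, planted differential fractions and
  a planted global downshift, contaminated interactome tables) with a
  complete ground-truth record, so every stage is testable without any
  raw mass-spectrometry data.

## Worked example

```bash
hlaquant simulate --seed 7 --outdir demo        # synthetic experiment
hlaquant run-all --fixtures demo --outdir demo/results
```

The run prints a JSON summary; with the default study conditions
(1200 peptides, 54% planted reduced / 5% increased, a −0.5 planted
global log2 shift, three replicates) the peptidome section reads:

```json
"peptidome": {
  "cascade": { "n_identified": 1200, "n_labelable": 763,
               "n_quantified": 518, "n_8_14": 484 },
  "differential": { "n_quantified": 484, "n_increased": 25,
                    "n_reduced": 268, "n_unchanged": 191,
                    "pct_increased": 5, "pct_reduced": 55 },
  "global_shift": { "median": -1.3342, "q1": -1.9012, "q3": -0.5258 },
  "length_mode": 9,
  "min_replicate_correlation": 0.9678
}
```

Reading: of 1200 identified peptides, 763 contain a Lys/Arg and can
carry the heavy label, 518 of those received a valid SILAC ratio, and
484 have canonical HLA class I length.  55% of quantified peptides are
called reduced and 5% increased (the planted fractions are 54%/5%),
the median log2 H/L is below zero — a global loss of presentation in
the heavy-labeled line — the modal peptide length is 9, and replicates
correlate at r > 0.96.  The same run reports 20.0% altered
interactions (10% + 10% planted) with 40% known-interactor recovery,
no peptidome–proteome correlation (r = −0.08) and a strongly positive
proteome–interactome correlation (r = 0.79, p < 1e-4), as planted.

Every number above is also available programmatically:

```python
from hlaquant import GeneratorConfig, generate_experiment, quantify_table

exp = generate_experiment(GeneratorConfig(seed=7))
quant = quantify_table(exp.peptide_table, "peptide")
```

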