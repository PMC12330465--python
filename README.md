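# immunoruler

Absolute quantification and heterogeneity analysis of MHC class I
immunopeptidomes from DIA mass-spectrometry search output.

## The problem

Label-free immunopeptidomics reports ion intensities, not molecule counts,
and when samples are tiny tissue fragments the number of cells per sample
varies wildly — raw intensities are dominated by input amount rather than
biology. `immunoruler` converts search-engine output (wide precursor and
protein-group matrices as produced by DIA-NN, plus the protein FASTA) into
**absolute antigen pseudocounts per cell**:

1. Precursors are filtered at a global protein-group q-value < 0.01 and
   charge/modification variants of the same peptide are summed.
2. The matched proteome is converted to copies per cell with the histone
   **proteomic ruler**: the summed histone MS signal corresponds to a known
   DNA mass per diploid cell (default 6.5 pg), so for protein *i* in
   sample *s*

   $$c_{i,s} = \frac{I_{i,s}}{\sum_{h \in \text{histones}} I_{h,s}}
   \cdot \frac{m_\mathrm{DNA}\,N_A}{M_i}$$

3. Each antigen's fraction of the total immunopeptide signal in its sample,
   $f_{j,s} = I_{j,s} / \sum_j I_{j,s}$, is scaled by that sample's
   per-cell copy number of beta-2-microglobulin (B2M) from the matched
   proteome: $n_{j,s} = f_{j,s} \cdot C^{B2M}_s$. One B2M molecule is
   required per surface peptide-MHC complex, so per-cell B2M bounds the
   presented repertoire and anchors the fractions on an absolute scale.

Both steps are within-sample ratios, so a global rescaling of any sample's
intensities (fragment size, cell input) cancels exactly, and per sample
$\sum_j n_{j,s} = C^{B2M}_s$ holds to machine precision.

On top of the quantification the package provides immunopeptidome QC
(length distributions, position frequency matrices and anchor-residue
information enrichment, protease-artifact screening, predicted-affinity
binder filtering at 100 nM), intratumoral heterogeneity statistics
(IQR/mean variability scores, antigen-vs-source-protein variability
concordance, per-sample z-score Pearson concordance, average-linkage
clustering), differential presentation testing (mixed MNAR/MAR imputation,
limma-style moderated t, Benjamini-Hochberg FDR, significance at
fdr < 0.05 and |log2FC| > 1), and a ground-truth simulator of matched
immunopeptidome + proteome datasets used throughout the test suite.

## Worked example

Simulate a 15-fragment dataset and run the full pipeline:

```bash
cat > cfg.yaml <<EOF
simulate:
  n_samples: 15
  n_proteins: 500
  n_antigens: 400
  frac_histone: 0.04
seed: 42
EOF
immunoruler all --config cfg.yaml --out run1
```

prints

```
conservation residual: 2.22e-16
outputs in run1 (config hash 2de2f3ebc952)
```

The conservation residual is the worst per-sample relative deviation of
summed pseudocounts from B2M copies — at machine precision by
construction. `run1/summary.json` reports, among other things:

```
"qc":  {"anchor_enrichment_bits": 4.24, "fraction_length9": 0.558, "n_peptides": 380}
"heterogeneity": {"variability_concordance": {"pearson_r": -0.011, "spearman_r": -0.006,
                  "n_pairs": 294}, "per_sample_r_median": 0.133}
```

4.24 bits of anchor enrichment means positions 2 and 9 of the 9-mers are
nearly fixed while the other positions are free — an HLA-like motif. The
variability concordance near zero says antigen presentation variability
across fragments is unrelated to source-protein expression variability,
which is exactly how the dataset was generated (the simulator's default
protein-presentation coupling is weak, `coupling_rho = 0.2`). Re-running
with `coupling_rho: 0.9` under `simulate:` drives the concordance up
(typically r ≈ 0.4 at this scale), and the pipeline reliably orders the
two regimes. Per-antigen tables (`pseudocounts_per_cell.tsv`,
`antigen_fractions.tsv`, `b2m_copies.tsv`, `copies_per_cell.tsv`,
variability and concordance tables) are written alongside.

Library use mirrors the CLI:

```python
from immunoruler.simulate import SimulationConfig, simulate_dataset
from immunoruler import analyze_tables

truth, immuno, proteome = simulate_dataset(SimulationConfig(seed=1))
result = analyze_tables(immuno, proteome, truth.proteome.records)
result.pseudocounts.pseudocounts   # antigen x sample, molecules per cell
```

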