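# Methods

## Quantification model

The pipeline assumes label-free DIA intensities are, within one sample,
proportional to the amount of analyte delivered to the instrument, with an
unknown per-sample proportionality constant (cell input, fragment size,
injection volume). Two within-sample ratios remove that constant exactly.

**Proteomic ruler.** Histones are stoichiometric with DNA, and the DNA
mass per diploid human cell is known (default 6.5 pg; configurable because
tumour ploidy varies). Protein-level MS signal is treated as proportional
to protein *mass*, so the summed histone signal calibrates signal per gram
and copies per cell follow as
`copies = I / sum(I_histones) * m_DNA * N_A / M`, with molar masses
computed from the FASTA sequence using average residue masses plus one
water (18.0153 g/mol). Histones are recognised by configurable
gene-symbol glob patterns covering human replication-dependent and variant
histone nomenclature. The ruler is computed per sample from the sample's
own matched proteome. Errors are raised, naming the sample, when a sample
has no histone signal or lacks B2M.

**B2M anchoring.** Stable surface expression of every peptide-MHC-I
complex requires one B2M molecule, so per-cell B2M copies bound the
presented repertoire size. Each antigen's fraction of its sample's total
immunopeptide signal (over *all* quantified peptides, before any length or
binder filter — filters apply downstream) is multiplied by that sample's
B2M copies per cell. Per-sample anchoring is the default because the
per-fragment analyses need each fragment on its own absolute scale; a
cross-sample-mean mode exists for experiments where a single global scale
is preferable. Missing antigens contribute nothing to the per-sample
total; fractions are over observed antigens only, so the conservation
identity `sum_j n_js = C_B2M,s` holds exactly on every input.

Zero intensities are treated as missing throughout: a zero ion intensity
is not observable in label-free DIA output, and keeping zeros would
distort fraction-of-total normalisation. Precursor aggregation (charge and
modification variants of one peptide summed; stripped sequence is the
default peptide key) propagates missingness only when every variant is
missing. Peptides shared between protein groups are kept as one row per
sequence; no deduplication against the proteome is attempted.

## Heterogeneity statistics

Per-feature variability across samples is IQR/mean on the untransformed
scale (scale-free; a log-space option exists). Quantiles use linear
interpolation between order statistics — the default convention of the
mainstream statistics environments ("type 7"). Features observed in fewer
than `min_samples` samples (default 8 of 15) get no score: the IQR of a
handful of values is dominated by noise. Antigen-protein concordance is
reported as both Pearson and Spearman over mapped pairs, since either
choice is defensible; multi-mapping or unannotated antigens are excluded
and counted. Per-sample concordance z-scores every feature across samples
first (zero-variance features dropped rather than producing infinities)
and reports within-sample Pearson r over mapped pairs, missing when a
sample has fewer than three complete pairs. Hierarchical clustering is
average-linkage on Euclidean distances of (by default) row-z-scored data,
refusing missing values rather than silently imputing; ties resolve by
input order so results are deterministic.

## Differential testing

Missingness is classified per feature and condition: missing in all
replicates = MNAR (below detection), missing in some = MAR. MNAR cells are
imputed by draws from `Normal(mu_s - 1.8 sd_s, (0.3 sd_s)^2)` per sample —
the Perseus/DEP down-shift convention — clipped at the sample maximum; MAR
cells by k-nearest neighbours over feature profiles (k = 10, Euclidean on
shared observed entries). A `knn_only` mode routes everything through kNN
for proteome-wide runs. One seed governs all draws. Testing uses a
moderated two-sample t: per-feature pooled variances are shrunk toward an
empirical-Bayes prior fitted by the method of moments on log variances
(scaled inverse-chi-square prior; trigamma inversion by Newton iteration),
with p-values on the augmented degrees of freedom, BH FDR, and the
significance rule fdr < 0.05 AND |log2FC| > 1. A plain Welch t is
available for transparency. No between-sample normalisation is applied by
default before testing: pseudocounts are already on a per-cell scale;
median-centering in log space is available for raw-intensity runs.

## Synthetic data

The generator emulates the statistical structure the analysis relies on,
with defaults at study scale: 15 fragment-like samples, 3000 proteins
(1% histones, plus B2M at 5e5 mean copies), 1500 antigens, 20%
measurement CV, left-censored missingness affecting ~20% of cells, 2%
random dropout, 5% of protein groups failing the 1% identification FDR,
and per-sample input scale factors with log-sd 0.8 (fragments differing
several-fold in cell content).

* Protein baselines are log-normal over ~2 natural-log units of dynamic
  range; each protein has its own across-sample deviation sd drawn
  log-normally around 0.4 — tumour fragments mix stable housekeeping
  proteins with immune/stromal proteins whose abundance tracks
  infiltration, so variability itself is heterogeneous. B2M's deviation sd
  is a separate parameter (default 0.25): it is a constitutive structural
  protein, and because anchoring transfers its trajectory to every
  antigen, it is a first-class study condition rather than a random draw.
* Histone copies are rescaled per sample so summed histone mass equals the
  configured DNA mass exactly, making the ruler invertible by
  construction; recovery tests therefore measure pipeline error, not
  generator slack.
* Antigens are tied to source proteins through a coupling parameter rho:
  per-sample log presentation deviation
  `tau_j * (rho * z_i + sqrt(1-rho^2) * eta)` with
  `tau_j = rho * sigma_i + (1-rho) * tau_ind`. At rho=1 an antigen
  reproduces its source protein's deviations exactly (pattern and
  magnitude); at rho=0 both are independent. The default rho=0.2 encodes
  largely decoupled presentation. True pseudocounts are normalised to sum
  to each sample's true B2M copies.
* Peptides are 8-12-mers peaked at length 9 (60%) with residues i.i.d.
  uniform except fixed anchors at position 2 (L) and the C-terminus (V);
  no proteome tiling is attempted.
* Rendering: proteome MS response is proportional to protein mass (the
  ruler's assumption), immunopeptide response to molecule count. Protein
  groups are split into precursors whose count grows with abundance
  (~5 + 1.5·log10 relative abundance, clipped to 2-10) — in real DIA data
  abundant proteins are quantified from many peptides — while
  immunopeptides get 1-3 charge/modification variants; split proportions
  are Dirichlet(2) (moderately uneven, like charge-state distributions)
  and fixed across samples, with independent log-normal noise per
  precursor and sample. Detection is logistic in log intensity (midpoint
  at the 20th percentile, slope 4 per natural-log unit), recovering a hard
  threshold as the slope grows; q-value failures are assigned per protein
  group (the filtered quantity is a global protein-group q-value) and
  never to histones or B2M, which in real data sit far from the 1% FDR
  boundary.

What the simulator does **not** model: retention time, m/z, spectral
interference, sequence-dependent response factors, proteome-tiled peptide
origins, decoy-based FDR mechanics, batch effects. Passing recovery tests
therefore shows the pipeline inverts its own generative assumptions under
realistic noise and censoring — not that those assumptions hold in any
particular real dataset.

## Problem sizes and numerical choices

Acceptance-level checks run at study scale where the property demands it
(ruler exactness and recovery at 3000 proteins x 15 samples across 20
seeds) and at a reduced scale of 300 proteins / 200 antigens for the
100-pair coupling-ordering comparison, a size at which the ordering is
already decided with margin. Null calibration uses 200 runs of 2000
features at 3 vs 3 replicates; per-run seeds are spawned from one base
seed via an RNG stream. Conservation and fraction sums are checked at
relative 1e-9 (achieved at ~1e-16); ruler recovery at 1e-6. TSV output
uses 17-significant-digit floats and round-trip parsing so write/read
cycles are bit-identical. Information content is computed without
small-sample correction by default, matching common ligandome logo
practice; a correction flag exists. The moderated-t prior fit falls back
to a point prior (normal tail) when the log-variance spread is smaller
than its sampling noise.

## Known limitations

The B2M anchor assumes B2M copy number is proportional to surface
peptide-MHC complexes; free intracellular B2M, HLA-F/E/G complexes and
shed B2M violate this proportionality and would bias absolute (not
relative) pseudocounts. The ruler assumes diploid DNA content unless told
otherwise. The moderated test supports exactly two conditions (direct
contrasts only). Cluster labels for subsetting "biologically relevant"
antigens are consumed from an external sequence-clustering tool; no motif
deconvolution is performed in-package, and binding-affinity predictions
are likewise inputs, not outputs.
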