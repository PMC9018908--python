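# Methods

## The problem

Droplet assays that read out surface proteins through oligo-conjugated
antibodies (CITE-seq, ASAP-seq, TEA-seq and relatives) report an antibody-
derived tag (ADT) UMI count per protein per droplet. Raw ADT counts carry
two technical noise components that mRNA-oriented normalizations do not
address:

1. **Protein-specific ambient noise.** Free, unbound antibody is
   encapsulated at droplet generation, so even droplets without a cell — and
   proteins a cell does not express — show positive counts. The magnitude is
   antibody-specific (concentration, clone stickiness) and is directly
   observable in the tens of thousands of empty droplets every droplet run
   produces.
2. **Cell-intrinsic technical noise.** Capture, lysis, reverse-transcription
   and depth effects scale every protein in a droplet up or down together.
   Total library size confounds this with real biology (cell size), but two
   independent readouts isolate it: isotype-control antibodies (no human
   antigen target) and the average level of each cell's *non-staining*
   protein background.

## The normalization

**Step I — ambient correction.** For each protein, compute the mean `mu_n`
and sample standard deviation `sigma_n` (n−1 denominator) of
`ln(count + P)` across empty droplets, then rescale cell counts:

    Y[p, i] = (ln(x[p, i] + P) − mu_n[p]) / sigma_n[p]

`P` is a pseudocount (default **10**) that guards the log at zero and
stabilizes the variance of small counts. A `Y` value reads as "standard
deviations above the expected ambient background" of that protein, which
zero-centers each protein's negative population. Proteins with zero
variance across empties carry no estimable ambient scale and are dropped
(with a logged warning) rather than floored — flooring would fabricate a
scale for a protein the empties say nothing about.

**Step II — per-cell denoising (optional, default on).** For each cell, a
two-component univariate Gaussian mixture

    f(y) = phi1 N(y | mu1, sigma1) + phi2 N(y | mu2, sigma2)

is fitted by EM over that cell's `Y` values; `mu1`, the mean of the lower
component, estimates the cell's background level. The noise matrix
`[mu1, isotype_1 .. isotype_q]` (columns z-scored across cells) is reduced
to its first principal component; each cell's PC1 score `lambda` is its
**technical component**. Per protein, an ordinary least-squares fit of `Y_p`
on the centered `lambda` is removed, returning intercept plus residuals, so
per-protein means are preserved exactly and residuals are orthogonal to
`lambda`. The PC sign is fixed so `lambda` correlates non-negatively with
the row mean of the scaled noise matrix ("more technical signal" is
positive).

Isotype controls are normalized and returned like any other protein but
remain flagged so downstream clustering can exclude them. Without isotype
controls, denoising can run on `mu1` alone (`use_isotype=False`), at
reduced robustness.

## Droplet selection and protein QC

Cell/empty partitioning uses the protein library-size distribution. With a
known cell-barcode list (e.g. the filtered matrix of an aligner), the
background is every other barcode with at least one protein read, capped
below the smallest cell library. Without one, a two-component mixture on
`log10(library size + 1)` finds the two modes; the background band ends at
`mu1 + 2 sigma1`, cells start at `mu2 − 2 sigma2`, and barcodes in between
are assigned to neither (ambiguous droplets contaminate either estimate).
If BIC prefers a one-component model, or the bands cross, the partition
refuses to guess and asks for explicit thresholds. A quantile-based QC
(default 0.995) trims oversized "background" droplets that are likely
cells. Proteins whose maximum UMI count across *cells* is below 5 are
removed from the whole matrix before normalization — the decision is made
on cell columns only.

## Mixture fitting details

* Model: k components, unequal variances, each variance floored at
  `1e-6 × sample variance` (min `1e-10`) so near-degenerate components
  degrade gracefully instead of inflating the likelihood without bound.
* Initialization: component j's mean starts at the `(j − 0.5)/k` sample
  quantile with a shared sample-SD sigma and equal weights — deterministic
  on the first start. Additional restarts (default 3 inside the pipeline)
  jitter the initial means with seeded Gaussian noise at half a sample SD;
  the best final log-likelihood wins, ties keeping the earlier restart.
* Convergence: absolute log-likelihood change below `1e-6` (max 200
  iterations). The per-iteration log-likelihood is asserted non-decreasing
  (tolerance `1e-9`); the reported log-likelihood always corresponds to the
  reported parameters.
* Constant input with k ≥ 2 returns a flagged fallback fit (all means equal,
  warning, no exception); in the pipeline such cells take
  `mu1 = mean of the values below the cell's median`.
* Model order is compared with `BIC = 2·loglik − (3k − 1)·ln(n)` (larger is
  better); ties break toward smaller k.
* Background mean for k ≥ 3 (used only in order-robustness checks): the
  extra component usually models a few tail proteins, not the background,
  so `mu1` is the mean of the *highest-weight* component among the k−1
  lower ones — the background is by construction the most numerous low
  population in a cell. For k = 2 this reduces to the lower component.
* Per-cell fits run in lockstep across cells (vectorized over a batch
  sharing the observation count), chunked at 8192 cells. Each cell's
  restart noise derives from `SeedSequence([master_seed, cell_index])`, so
  results are independent of chunking and bit-identical to fitting each
  cell separately — verified in the test suite. 50,000 cells × 90 proteins
  normalize end-to-end in about a minute within ~0.6 GB.

## What the synthetic generator emulates

`generate()` draws a per-protein ambient rate `a_p ~ LogNormal(ln 8, 0.5)`,
a mean-one per-cell technical factor `c_i` (log-SD 0.5) and a mean-one
per-empty-droplet efficiency `e_j` (log-SD 0.5). Empty droplet counts are
negative binomial with mean `e_j · a_p`; cell counts with mean
`c_i · a_p · (1 + s_p · mask[p, type(i)] · signal_strength)`, where the
positivity mask marks the 25% of phenotyping proteins each of 4 cell types
stains for, `signal_strength = 40` and `s_p` is a mild (log-SD 0.2)
per-protein signal modifier. Overdispersion is 0.1 (`Var = m + 0.1 m²`);
0 gives the exact Poisson limit. Isotype controls are never positive.
Defaults: 90 proteins including 4 isotype controls, 2000 cells, 20000
empties.

Rationale for the free parameters (neither the assay nor the method fixes
them): the ambient scale (median 8 counts per protein per empty droplet,
0.5 log-spread) keeps counts out of the near-zero discrete regime — below
~2 counts per droplet, the median of *any* standardized log count sits up
to ~0.75 SD from its mean purely from integer discreteness (empty droplets
themselves show the identical offset), which says nothing about the
normalization. The shared 0.5 log-spread for `c_i` and `e_j` encodes the
model's core empirical premise that empty droplets are exchangeable with
unstained cells up to the same capture-efficiency variation. A 40-fold
signal at 25% positivity separates cell and empty library sizes by the
order of magnitude seen in real runs.

What the generator does **not** emulate: doublets and hashing artifacts,
protein–protein count correlations beyond the shared cell factor,
antibody-specific binding kinetics, sequencing-depth saturation, or an
mRNA modality. Passing tests therefore demonstrate the estimators recover
the stated generative structure — not that real panels satisfy that
structure; the diagnostics module (`assumption_report`) exists to check
the assumptions on real data.

## Numerical and design choices

* Natural log everywhere in the ambient profile; sample SD (n−1) for
  `sigma_n` — small background samples bias the population SD.
* Noise-matrix columns are centered and unit-scaled before the PCA, making
  `lambda` invariant to per-column rescaling; `mu1` and isotype levels are
  on comparable but not identical scales.
* `lambda` is exactly mean-centered before the regression, so "residuals
  plus intercept" preserves every protein's cross-cell mean to machine
  precision.
* One user seed drives all randomness; per-cell seeds are derived from it,
  so serial, chunked and batched execution agree bit for bit.
* The positivity convention used in the diagnostics is a uniform threshold
  of 3.5 (i.e. 3.5 ambient SDs, ± the technical-component adjustment).

## Known limitations

* The automatic droplet split assumes a bimodal library-size distribution;
  barcode-rank "knee" data with a long ambiguous shoulder should be
  partitioned with an explicit range or an external cell list.
* With very few isotype controls (or none), `lambda` leans on `mu1` alone
  and can absorb some biological signal in cells whose background/positive
  split is ambiguous.
* Panels in which most ambient rates are below a few counts per droplet
  put step I in the discrete-count regime, where "SDs above background"
  is a coarse statement for those proteins.
* Problem sizes in the test suite (400–2000 cells for property checks,
  one 50,000-cell end-to-end run) were chosen as the smallest at which the
  measured correlations stabilize.
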