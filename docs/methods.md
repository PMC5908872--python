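# Methods

## Problem and scope

The pipeline compares the transcriptomes of tumor groups and cell-line
groups against a common control group, from a raw gene × sample count
matrix to pathway-level dysregulation maps. It deliberately starts at the
count matrix: alignment, read counting and QC are upstream concerns, and
gene length is unknown to the pipeline (no TPM/FPKM). All stages operate
on three inputs — counts TSV, sample sheet TSV, gene sets GMT — and one
designated control group.

## Expression filtering

Two stages, applied in order:

1. **Detection**: keep genes with ≥ 1 read in ≥ 1 library. The set of
   genes passing only this stage is the *detected universe*, which is also
   the denominator population for pathway scoring.
2. **Low-expression percentile cut** (default q = 0.40): within each
   sample and separately for each biotype (protein-coding, miRNA, lncRNA),
   the q-th percentile of library-size-normalized counts is computed over
   that biotype's genes; a gene is kept iff its normalized count strictly
   exceeds the threshold in at least one sample.

Pinned conventions, since the filter's verbal definition leaves them open:

* Percentile = linear interpolation between order statistics at index
  (n−1)·q ("type 7", numpy's default). Chosen for ubiquity and
  bit-reproducibility.
* The percentile population is all detected genes of the biotype,
  zeros included. (Whether zeros should be excluded is genuinely
  ambiguous; including them is the simpler reading and is pinned.)
* "Normalized by library size" defaults to division by median-of-ratios
  size factors; a total-count alternative (`--norm total-count`) exposes
  the simpler reading.
* Strict inequality ("above" the percentile).

## Differential expression

The model for gene g in sample j of group G is

    K_gj ~ NB(mean = s_j · m_gG, variance = mean + α_g · mean²)

* **Size factors** s_j: median over genes (nonzero in all samples) of the
  ratio of the sample's count to the gene's geometric mean, rescaled to
  geometric mean 1 (checked to 1e-9).
* **Dispersion** α_g: method of moments on normalized counts — pooled
  within-group variance over all groups with ≥ 2 replicates, grand mean
  over the same samples, α̂ = max(0, (var − mean)/mean²) — then shrunk
  toward a trend α(μ) = a₀ + a₁/μ fitted across genes by non-negative
  least squares. The shrinkage weight defaults to 0.5: the raw per-gene
  estimate has large sampling variance at these replicate numbers, and
  without shrinkage, genes whose variance is underestimated by chance
  produce inflated Wald statistics. One dispersion per gene is shared by
  all contrasts.
* **Group means**: the log-link MLE of each group's mean is a
  one-dimensional root of the NB score equation
  Σ_j (y_j − s_j m)/(1 + α s_j m) = 0, which is strictly monotone in m;
  it is solved by damped Newton iteration in log m, vectorized over
  genes. A group with all-zero counts has its mean floored at half a
  count over the group's total size factor: the fold change stays finite
  and the enormous standard error makes the test appropriately powerless.
* **Wald test**: log2fc = (log m_G − log m_ctrl)/ln 2; the variance of
  each fitted log-mean is the inverse expected Fisher information
  Σ_j μ_j/(1 + α μ_j); p is the two-sided standard-normal tail. A
  non-converged fit yields p = NA; such genes are excluded from that
  contrast's BH vector and reported, to avoid silent rank distortion.
* **Multiple testing**: Benjamini–Hochberg step-up per contrast (matching
  per-comparison adjustment conventions for this design), calls at
  FDR ≤ 10⁻⁵: up if q ≤ α_FDR and log2fc > 0, down if log2fc < 0,
  otherwise ns.

A single-replicate group (the design includes one, GL-1-like) is handled
by construction: it contributes nothing to dispersion estimation, and its
contrast relies on the trend-informed shared dispersion and the control
group's information.

The reported log2fc is the GLM coefficient difference. Regularized-log
transforms (used by some published analyses for *display* of fold
changes) are replaced by the simpler log2(normalized + pseudocount)
surrogate, used only for PCA input; the tested quantity is always the
GLM coefficient. Exact numerical agreement with any specific DE package
is a non-goal — correctness is established by calibration on null data
and recovery of planted effects.

## Concordance analysis

Direction calls form a gene × group matrix over {+1, −1, 0}. "Unchanged"
means d = 0 (no call at the FDR cutoff); no effect-size band is imposed.
Venn partitions assign each called gene to the exact combination of
calling groups, separately for up and down calls. Consistency classes
compare a reference group against comparison groups: concordant_up if the
reference is up and every comparison is up or unchanged; mirrored for
down; otherwise discordant. The all-group core is restricted to genes
called in every group and split by uniform vs mixed sign. Percentages are
reported against the reference group's called-gene counts.

## Pathway net expression

NE_pG = (n_up − n_down)/n_detected ∈ [−1, 1], where n_detected counts the
pathway's members in the detected universe (detection filter only — genes
removed by the percentile filter still count in the denominator, as
detected-but-not-called). Pathways with n_detected < 20 are dropped.
The detected-size denominator is pinned deliberately; published summaries
derived from annotated pathway sizes can differ slightly from the
detected-denominator value (e.g. a 17-up/1-down pathway of 32 detected
genes scores exactly 0.50 here), and no printed variant of such values is
asserted as ground truth.

Bands: near-zero |v| ≤ 0.05, negative v < −0.10, positive v > 0.10. The
interval 0.05 < |v| ≤ 0.10 is labelled "weak" so that classification is
total; that band is an artifact of making the labels exhaustive.

## Self-organizing map

A from-scratch online Kohonen SOM on a 4 × 4 hexagonal grid (unit (r,c)
at x = c + 0.5·(r mod 2), y = r·√3/2; nearest-neighbor distance 1; units
numbered 1..16 row-major). Since published uses of SOM packages rarely
print their "default parameters", the hyperparameters are pinned here:
100 epochs; learning rate 0.05 → 0.01 and neighborhood radius (half the
grid diagonal) → 1.0, both decaying linearly; Gaussian neighborhood
exp(−d²/2r²) on grid distance; Euclidean BMU with ties to the lowest
unit index; codebook initialized by sampling data rows; presentation
order reshuffled each epoch. One seeded generator drives initialization
and shuffling, so a seed fully determines the model. Net expressions
already share the [−1, 1] scale, so inputs are not standardized. The
original grid numbering/orientation of any particular published map is
not reproducible without its seed; clustering quality is instead
assessed by quantization error and by topology preservation of planted
archetypes.

## PCA summary

PCA of samples over the DEG union (genes called in ≥ 1 contrast): each
gene's moderated-log expression row is centered and scaled to unit
variance (zero-variance genes dropped and logged), components come from
the SVD of the sample × gene matrix, and explained-variance fractions are
σ_i²/Σσ_j². Each loading vector is oriented so its largest-magnitude
element is positive, making signs deterministic across linear-algebra
backends.

## Synthetic data

The generator emulates the target study's design: seven disease/cell-line
groups with replicates {B-cell lymphoma 12, probable T-cell lymphoma 4,
CLBL-1 5, CLBL-1M 5, GL-1 1, OSW 4, CL-1 2} plus 4 controls (37
libraries). Defaults, chosen once as desk-scale realistic values:

* Genes: 2,000 protein-coding, 150 miRNA, 600 lncRNA (scaled-down
  stand-ins for the ~19.9k/0.8k/8.1k annotated classes); 10% of genes are
  never expressed (μ = 0), mimicking undetected annotation.
* Baseline means log-normal — meanlog log 150, sdlog 1.3 for
  protein-coding; log 15, sdlog 1.0 for miRNA/lncRNA (non-coding classes
  sit lower, exercising biotype-stratified filtering).
* Dispersion α ~ Gamma(2, 0.05) (mean 0.1, a typical bulk RNA-seq
  scale); library-size factors log-normal (sdlog 0.15).
* Planted log2 fold changes: magnitudes uniform on [0.5, 5] (published
  fold-change distributions concentrate in [−2, 2] with tails beyond
  ±5). Pools are disjoint: 40 core-up and 40 core-down genes (DE in all
  seven groups), 40 exclusive genes per group (random sign), 40
  cell-line-only down genes, and 2 discordant genes (up everywhere, down
  in GL-1 — emulating single-cell-line sign flips). Planting is
  restricted to protein-coding genes with μ ≥ 20 so planted effects are
  detectable in principle.
* Pathways: 8 each of the archetypes all_negative, all_positive,
  near_zero and cell_line_only (sizes 22–45; half the members from the
  matching planted pool, the rest null) plus 28 unconstrained background
  sets (sizes 10–60, so some fall below the 20-detected-gene rule).
  By construction, net expression computed from the TRUE direction
  labels reproduces each archetype's sign pattern exactly.

Counts are drawn by the gamma–Poisson mixture, so the NB mean/variance
parameterization is exact. What the simulator does **not** emulate:
correlated genes (co-expression), GC/length biases, outlier samples,
batch effects, or realistic gene/pathway naming. Tests passing on this
generator therefore demonstrate the pipeline's statistical correctness
under its own model assumptions, not robustness to real-data artifacts.

## Problem sizes and numerical choices

The test and acceptance workloads use desk-scale sizes chosen to exercise
every code path with comfortable margins: 2,000-gene null calibration
over 20 seeds, 800-gene recovery studies, 200–1,000-instance brute-force
oracle comparisons, and 10-seed SOM topology checks. Newton iterations
cap at 100 with steps clipped to ±5 on the log scale (the score is
monotone, so clipping only slows, never misdirects, convergence);
convergence tolerance is 1e-12 on the relative score. Real-valued tables
are serialized with %.17g so write-then-read round trips are exact.

## Known limitations

* The Wald test uses the normal approximation; with very few replicates
  its p-values are approximate, which is why the strict FDR ≤ 10⁻⁵
  cutoff and the calibration suite matter.
* The dispersion trend a₀ + a₁/μ is a deliberately simple two-parameter
  fit; it does not model dispersion heterogeneity beyond the mean trend.
* Net expression treats a pathway as a bag of genes: no topology,
  no gene weighting, no enrichment statistic — by design.
* The SOM is the classic online variant; batch training and toroidal
  grids are out of scope.
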