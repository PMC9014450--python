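# Methods

`spothet` implements a spot-level analysis of heterogeneous drug response
in spatial transcriptomics of the kidney: per-spot cell-type composition is
estimated from a single-cell signature, expression is attributed to a
target cell type by fraction normalization, minority populations are
located by lattice adjacency, and per-structure response heterogeneity is
screened with skewness ranking against a Gaussian null. A synthetic tissue
generator with planted ground truth backs every stage with verifiable
recovery tests.

## The mixing model and deconvolution

A Visium spot covers several cells, so its transcriptome is modelled as a
linear mixture of cell-type profiles:

    E[c_j] ∝ S f_j,   f_j ≥ 0,  Σ_t f_jt = 1

where `S` is the genes × types signature matrix (mean counts-per-10k of
QC-passed, library-size-normalized reference cells) and `f_j` the spot's
cell-type fractions. Fractions are estimated per spot by non-negative
least squares on the counts-per-10k spot profile over the genes shared
with the signature, then renormalized onto the simplex. The initial fit is
refined by two iteratively reweighted passes with inverse-variance weights
`1/sqrt(mu + theta mu^2 + 1)` computed from the *fitted* means, with the
overdispersion `theta` estimated per spot from squared residuals by method
of moments. Weighting by fitted rather than observed values matters:
weights taken from the observed counts up-weight downward noise
fluctuations and bias the fit. Working in counts-per-10k makes the
estimate invariant to the spot's library size; mixing is modelled in
linear space because transcript counts add linearly. All-zero spots are
flagged degenerate (NaN rows) rather than silently imputed.

This NNLS estimator is a transparent stand-in for SVR-based cell-fraction
tools built on the same mixing model; numerical agreement with those tools
is not claimed, and their batch-correction modes are out of scope.

## Reference QC and signature construction

Reference cells are kept when they have 200–5,000 detected genes
(inclusive), fewer than 30,000 total UMIs (strict) and under 40%
mitochondrial counts (strict); mitochondrial genes default to the rat
`Mt-` prefix and can be overridden. The filter is idempotent and preserves
cell order. Signature columns are means of per-cell counts-per-10k, so
each column sums to 10,000 and matches the linear mixing model. Marker
tables use one-vs-rest Wilcoxon rank-sum on normalized values,
Benjamini–Hochberg adjustment within type, and log2 fold change of
pseudocounted means, ranked by fold change.

## Fraction-normalized expression

For a target cell type with estimated fraction `F_j` per spot, expression
attributed to that type is

    NC_ij = C_ij / F_j

computed over the spots with `F_j ≥ min_fraction` (default 0.05; the
threshold behind "a relevant fraction" is a free parameter and is logged
in the output metadata). `C` is the raw count matrix: a
variance-stabilized `C` would change values but not the algebra, and the
subsequent total-count step absorbs per-spot scale. NC is then total-count
normalized and log-transformed per spot:

    value_ij = log(1 + scale · NC_ij / Σ_i NC_ij),  scale = 10,000.

Because `F_j` is a per-spot scalar, it cancels exactly in the total-count
step; the fraction threshold therefore does the real work of restricting
analysis to spots where the target type is genuinely present, while the
division makes the intermediate NC interpretable as type-attributed
counts. All downstream screening (skewness, KS, responder ranking)
operates on the log-normalized values — a design choice made after
observing that screening the linear NC scale is dominated by the
right-skewed `1/F̂` estimation noise common to every gene, which masks
gene-specific tails.

## Spatial adjacency and dominant-score classification

Spots sit on the Visium hexagonal array: row and column parity are equal
and the six neighbours are at offsets (0, ±2), (±1, ±1); spots in
different capture areas are never adjacent. Cortical spots with a nonzero
score for either of two sub-populations (e.g. the two thick-ascending-limb
populations TAL-1 and TAL-2) are classified by the strictly-greater rule —
group A only when its score is strictly higher, ties to group B — and the
groups are compared for glomerulus adjacency (≥ 1 hex neighbour annotated
as glomerulus, glomerulus spots themselves excluded) in a 2×2 Fisher exact
test, two-sided by hypergeometric probability mass. "Adjacent" means
shares a hex edge, not a two-ring neighbourhood.

## Heterogeneity screen and responder classification

Per gene, across the eligible (fraction-selected, glomerulus-overlapping)
spots of the treated arm, the screen computes the population-moment
skewness `g1 = m3 / m2^{3/2}` and flags the `ceil(top_frac · n)` highest
among genes whose mean exceeds `min_mean` (defaults 0.05 and 0.01; ties
broken by gene id). Normality of the response-gene distribution is tested
per sample with a one-sample Kolmogorov–Smirnov test against a Gaussian
with the sample's own mean and SD; p-values use the asymptotic KS
distribution, which ignores parameter estimation and is anti-conservative
— a Lilliefors-corrected variant is available.

Spots are labelled *Responding* when their normalized response-gene value
strictly exceeds a threshold. `classify_responders` takes the threshold
explicitly (default 0, i.e. detected vs not); the pipeline derives it from
the control arm as the 95th percentile of control values. The rationale:
when the response gene has appreciable basal expression, detection
saturates in both arms and carries no contrast, whereas "above what
untreated tissue shows" remains meaningful at any basal level and is
exact-test calibrated under the null (both arms then exceed the reference
quantile at the same rate). The responder-by-condition contrast uses the
same Fisher exact test. Per sample, the `ceil(0.25 · n)` spots with the
highest normalized response values (ties by spot id) are flagged
*high-responding*; samples are ranked independently so a globally strong
sample cannot absorb the quota of a weak one. Differential expression
between high-responding and other treated eligible spots uses Wilcoxon
rank-sum per gene (exact null when the smaller group has ≤ 8 observations
and no ties, tie- and continuity-corrected normal approximation
otherwise), BH adjustment, and fold-change ranking.

## Synthetic tissues

The generator emulates the two-arm rat kidney study the pipeline is
designed around. Defaults, and why:

| parameter | default | rationale |
|---|---|---|
| conditions | 3 Ctrl + 3 Losa sections | mirrors the study's three rats per arm |
| lattice | 40 × 30 spots, 4 equal zone bands | cortex band large enough for 40 spaced glomeruli |
| n_glomeruli | 40 per section | sparse single-spot glomeruli, unambiguous truth |
| glomerulus profile | podocyte 0.5 / mesangial 0.3 / JG 0.2 | free parameters; spot-level composition of real glomeruli is not established |
| macula densa | one TAL-2-enriched spot (fraction 0.6) per glomerulus, hex-adjacent | the anatomical feature the adjacency analysis must recover |
| depth_mean_umi | 5,000 | typical Visium spot depth |
| nb_dispersion | 0.05 | UMI counts are near-Poisson at spot level; one shared knob |
| depth_cv | 0.2 | log-normal library-size variation, mean exactly 1 |
| marker_share | 2% of a type's transcriptome per marker, 2% leak | renal marker genes (e.g. renin in JG cells) are highly expressed |
| effect_ren_fold | 5, in the JG component of planted high-responders only | the planted heterogeneous response |
| effect_ptgs2_fold | 3, in every treated macula densa component | the planted homogeneous arm-wide response |
| high_responder_frac | 0.25 | matches the top-quartile selection rule |

Counts are gamma–Poisson: `lambda ~ Gamma(1/theta, theta·mu)`, `count ~
Poisson(lambda)`, reducing to Poisson as `theta → 0`. Gene panels contain
300 genes: named analogs (*Ren*, *Ptgs2*, *Pappa2*, *Slc12a1*, *Rplp0*,
`Mt-1..5`), five exclusive markers per type, and log-normal baseline genes.
Zone mixtures are Dirichlet draws over zone-affine types with
concentration proportional to affinity weights. A `md_placement="random"`
mode scatters the macula-densa-profile spots uniformly over the cortex as
the null for the adjacency analysis.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: transcriptome-wide co-expression structure,
doublets and ambient RNA, segmentation error in histological annotation,
multi-spot glomeruli, per-gene dispersion variation, and batch effects
between sections. Recovery results on these tissues demonstrate the
correctness and calibration of the pipeline's logic, not field
performance on real Visium data.

## Numerical choices and degenerate inputs

- Fraction rows must sum to 1 within 1e-9; degenerate spots are flagged,
  never renormalized silently.
- Fisher tests with a zero margin return p = 1 (every table equally
  probable) rather than erroring.
- Constant vectors have undefined skewness and are flagged, not NaN.
- Quantiles use linear interpolation (numpy default); the top-skew set is
  defined by rank with id tie-break so it has exactly `ceil(top_frac·n)`
  members regardless of ties.
- Analysis on the 300-gene synthetic panel uses `min_genes=100` in QC:
  the 200-gene lower bound assumes a genome-wide panel and would exclude
  every cell when only 300 genes exist. The literal study thresholds
  remain the defaults.
- Problem sizes in the test suite (sections per arm, seeds per
  replicate set) are scaled so the full suite completes in minutes while
  keeping every planted-recovery check at the study's stated effect sizes.

## Known limitations

- NNLS fractions are a stand-in for the SVR-based tool used in the
  original workflow; absolute fraction scales may differ even where
  rankings agree.
- The asymptotic KS p-value with estimated parameters is
  anti-conservative; use the Lilliefors option for calibrated normality
  p-values.
- The responder threshold rule (control 95th percentile) is a package
  design choice; the detected-vs-not rule is available by passing
  `threshold=0` explicitly.
- Homolog mapping drops one-to-many pairs rather than aggregating them.
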