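# Methods

## The problem

A gene switch is a gene whose regulatory feedback — cooperative positive
autoregulation, or mutual repression between two genes — gives it two
stable expression states. Sampled across many conditions, such a gene
settles into one attractor or the other, so its expression profile across
a compendium is *bimodal*, while ordinary graded genes produce unimodal
profiles. switchscan turns this into a mining procedure: score each
gene's profile for bimodality, ask whether one of the two states is
specific to a target phenotype, validate on an independent paired
dataset, and classify the switch pattern. Bundled ODE simulators of
canonical bistable circuits provide synthetic compendia with known
planted switches, so every stage is testable without external data.

## Bimodality score: ΔAIC from Gaussian-mixture fits

Each gene's profile x₁…x_n (log2 scale, missing values dropped, n ≥ 6) is
fitted with

* one Gaussian: MLE mean and variance (1/n convention), k = 2 free
  parameters, log-likelihood in closed form;
* a two-component Gaussian mixture by EM: k = 5 free parameters (two
  means, two variances, one weight).

With AIC = 2k − 2 log L, the score is ΔAIC = AIC₁ − AIC₂. Large positive
values mean the bimodal description is decisively better. ΔAIC is a
*ranking* statistic; where a binary call is needed the conventional
strong-support cutoff ΔAIC > 6 is used, but the screening pipeline cuts
by rank (top 10%), not by this threshold.

EM details that matter:

* **Restart scheme.** Ten restarts by default: one *collapsed* start
  (both components equal to the single-Gaussian fit — an exact EM fixed
  point, which guarantees log L₂ ≥ log L₁ and hence ΔAIC ≥ −6 on every
  input), one median split, and eight random quantile splits of the
  sorted data. Split-type random starts are used instead of random
  responsibilities: responsibilities drawn per sample put both initial
  components at nearly the overall mean, from which one-dimensional EM
  separates pathologically slowly (hundreds of iterations even on
  clearly bimodal data); quantile splits start well-separated, explore
  distinct basins, and converge orders of magnitude faster.
* **Canonical form.** EM runs on a standardized copy of the profile,
  reflected so the third central moment is non-negative and sorted
  ascending; fitted parameters are mapped back through the affine
  transform. Consequences: ΔAIC is exactly equivariant under any affine
  map ax + b (a ≠ 0, including reflections) whenever the profile has
  nonzero skew, and exactly invariant to sample order. Moments are
  computed on the sorted array so even float rounding is
  permutation-stable.
* **Convergence and floors.** |Δlog L| < 1e−8 or 500 iterations;
  variance floor 1e−6 × the profile variance (1e−12 absolute for
  constant profiles) prevents single-point collapse. If no restart
  converges the best iterate is kept and flagged.
* **Determinism.** `score_matrix` seeds gene i's generator from
  (global seed, i); genes with equal observed counts are batched through
  one jointly vectorized EM pass (chunks of 32), which is bitwise
  identical to per-gene fitting but amortizes per-operation overhead.

Mode assignment: each sample goes to the component with the larger
posterior responsibility; exact ties go to the high (larger-mean) mode,
biasing toward calling the ON state. Excess kurtosis (plug-in m₄/m₂² − 3)
and the fitted-component separation |μ₁−μ₂|/√((σ₁²+σ₂²)/2) are reported
alongside for comparison with those simpler bimodality criteria.

## Conditional separation D

For a target condition, D = |μ₁ − μ₂| / √((σ₁² + σ₂²)/2) between the
target samples and all remaining samples, with 1/n SDs (the 1/n vs
1/(n−1) choice is immaterial at compendium sample sizes but keeps the
statistic coherent with the MLE likelihoods). D > 1.8 — "greater than or
close to 2" — flags a distinct target-specific state. D is computed on
log2-scale intensities.

## Information gain

Phenotype uncertainty is the plug-in Shannon entropy H(X) in bits. A
gene's expression is discretized into equal-frequency bins (quantile
cuts; tied edges collapse bins deterministically rather than splitting
ties; default 4 bins). The percentage gain 100·(H(X) − H(X|Y))/H(X) is
base-invariant, and the bin count shifts absolute entropies without
affecting between-gene comparisons. No small-sample bias correction is
applied (plug-in throughout). Gain is undefined (an explicit error, not
NaN) when the phenotype has a single class.

## Screening pipeline

1. Rank all scoreable genes by ΔAIC (ties broken lexicographically by
   gene id) and keep the top ⌈0.10·G⌉.
2. Compute D for the target phenotype against all other samples;
   `passed_screen` ⇔ D > 1.8.
3. Validate on an independent paired tumor/normal dataset: refit the
   two-component mixture on the pooled validation samples, assign modes,
   and test the 2×2 mode-by-group table with a two-sided Fisher exact
   test, Benjamini–Hochberg adjusted across tested genes; adjusted
   p < 0.05 validates. The pairing defines the two groups; a matched
   (McNemar-style) test is deliberately out of scope.
4. Classify using the global fit's mode occupancies restricted to target
   samples: **type 1** when both modes each hold ≥ 15% of the target
   samples (bimodal within the phenotype, the estrogen-receptor-like
   pattern); **type 2** when ≥ 90% of target samples sit in one mode and
   the other samples are ≥ 90% in the opposite mode (phenotype-locked).
   The thresholds make the rules mutually exclusive (a 90% major mode
   leaves at most 10% < 15% in the minor mode).

Mode enrichment (the yeast-style analysis) asks, per fitted gene, whether
a mode over-represents a condition category: one-sided hypergeometric
upper-tail probability for each (mode, category) pair, BH-adjusted across
pairs.

## Circuit simulators

Two printed circuits plus one composite network:

* **Self-activation switch** (one gene):
  dA/dt = pA²/(1+A²) · 1/(1+R²) − A/2.5 − dA, with repressor
  R(i) = 10(1−Ki)/(1+Ki) controlled by stimulus i. Defaults p = 4,
  K = 0.03, d = 0.1 put the circuit in a bistable regime: A = 0 is
  always stable (production needs A), and a high attractor exists when
  repression is weak (R < √3). Both the A/2.5 loss and the linear
  degradation dA are applied as separate sinks.
* **Toggle switch** (two genes): dA/dt = α/(1+B²) − dA and symmetrically
  for B; defaults α = 10, d = 1 give mirror attractors near (9.899,
  0.101) with the diagonal as separatrix.
* **Stand-in network**: one self-activation switch gene, one
  Hill-activated effector (inherits the all-or-none response), and
  n graded genes with production linear in the stimulus — the
  qualitative switch/effector/graded trio of a serum-response network.
  `with_graded_genes` appends such graded responders to any circuit.

Integration is classic fixed-step RK4, h = 0.01, stopping early when the
max-norm of the vector field drops below 1e−6 (or at t_end = 500);
fixed-step integration makes every trajectory bit-reproducible.
Unconverged trajectories are flagged, included, and logged. Batched
integration (many cells/clones/genes in one vectorized pass) is
numerically identical to row-by-row integration.

Hysteresis is probed by a quasi-static stimulus sweep up then down,
carrying each steady state over with a small basal floor (0.2) — a cell
never restarts from exactly zero protein, and without the floor the
absorbing A = 0 state would mask switch-on. The bistable window is
reported where the two sweeps disagree by more than half their maximal
discrepancy.

## Synthetic-data generator

`generate_dataset` emulates a condition compendium: per clone it draws a
perturbed parameter set (multiplicative Gaussian noise, CV 0.20 per the
canonical protocol, truncated at 10% of nominal so rates stay positive),
a uniform initial state per gene, a stimulus, and `cells_per_clone`
cell-level initial states (Gaussian around the clone state, CV 0.10,
truncated at 0); the readout is log2(mean steady state + 1) plus optional
measurement noise. Defaults are 100 clones × 100 cells. A single seeded
generator streams all draws in the documented order (parameters → init →
stimulus → cells → noise), so a dataset is a pure function of (model,
config, seed). Uniform initial bounds default to [0, 12], chosen to
straddle both toggle basins; both fixed and per-clone-random stimuli are
supported via stimulus samplers.

What this emulates — and what it does not: clone-to-clone kinetic
variability, population averaging (which converts all-or-none single-cell
switching into apparently graded bulk responses when cells straddle a
separatrix), and log-scale measurement noise. It does not model
stochastic gene expression (no SSA), batch effects, probe-level artifacts
or normalization bias, so passing tests demonstrate the method's behavior
under its own statistical assumptions, not robustness to real microarray
pathology.

`generate_compendium` builds the end-to-end benchmark: 1,000 genes × 300
samples with a 100-sample target ("cancer") block, 20 planted type-2
switches (driven into the monostable-ON regime, stimulus 33, throughout
the block; OFF elsewhere), 10 planted type-1 switches (bistable-window
stimulus 30 inside the block with initial conditions U[0, 1.15]
straddling the separatrix at ≈ 0.2, giving an ≈ 80/20 ON/OFF split; OFF
elsewhere), and 970 null genes (half graded responders, half
housekeeping). Design notes:

* Parameter noise is CV 0.10 here. At CV 0.20 the stimulus coupling K
  drifts far enough that ~10% of intended-ON samples fall outside the
  circuit's ON window (Ki ∈ (0.71, 1.42)) and lose the high attractor —
  the generator would then not deliver its own planted truth. The
  calibration was done once against the bifurcation structure.
* Null graded genes use the exact closed-form steady state of their
  linear kinetics (gain·i/d) rather than numerical integration —
  identical values, and it keeps the 10-replicate benchmark fast.
  Planted switch genes are always integrated numerically.
* A paired validation set (40 tumor/normal pairs) is generated from the
  same gene set with the same planting rules.

## Numerical choices and degenerate inputs

* Variance floors as above; constant profiles collapse cleanly to
  ΔAIC = −6.
* D with both groups at zero variance: 0 if the means agree, ∞ otherwise.
* Equal-frequency binning with heavy ties collapses bins (flagged) but
  always assigns every sample exactly one bin.
* Fisher/hypergeometric p-values come from scipy; BH adjustment from
  `scipy.stats.false_discovery_control`.
* All results tables are written deterministically (sorted, 6 significant
  digits) with a provenance header (version, seed, config hash).

## Problem sizes used by the test and acceptance runs

Attractor capture uses 1,000 random initial states; EM recovery 20 seeds
at n = 1,000; the null matrix is 2,000 genes × 200 samples; bimodality
emergence 20 replicate 100-clone datasets; the recovery benchmark 10
compendium replicates (30 planted switches each). The hysteresis sweep
uses 26 stimulus points over [10, 35]. These sizes were chosen as the
smallest that make the stochastic checks statistically stable.

## Known limitations

* The two-component mixture cannot represent more than two expression
  states; genes with three-state dynamics would be scored against the
  best two-state description.
* ΔAIC's null distribution depends on n; the ΔAIC > 6 convention is a
  support heuristic, not a calibrated p-value — which is why the pipeline
  screens by rank.
* EM on exactly symmetric (zero-skew) profiles loses the reflection
  canonicalization guarantee; affine equivariance then holds only up to
  the usual EM restart sensitivity.
* The validation stage treats pairs as defining two groups; it does not
  exploit within-pair correlation.
* Fixed-step RK4 with h = 0.01 is accurate for the bundled circuits
  (step-halving changes steady states by < 1e−6) but is not adaptive;
  stiff user-supplied circuits may need a smaller step.
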