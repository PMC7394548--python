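# Methods

## The quantal model and the PhTx perturbation

Each simulated NMJ draws a quantal size *q* (mean miniature amplitude, mV)
and a quantal content *QC* (vesicles per stimulus) from gamma distributions
parameterised by (mean, CV). Gamma was chosen because both quantities are
strictly positive and their empirical histograms are right-skewed; the
distributional family is a package choice, not a measured fact. The evoked
EPSP is `QC × q`, reported with multiplicative Gaussian measurement noise of
CV `meas_cv` (mean-preserving; clipped far below zero crossing).

PhTx is modelled purely as a multiplicative scaling of quantal size by
`phtx_scale` (φ, default 0.5). Nothing in the underlying physiology pins φ
numerically; 0.5 is a configurable default chosen to halve the quantal size,
a conveniently strong but sub-blocking perturbation. Homeostatic
compensation is linear in a single parameter *h* (`compensation`): under
PhTx, QC is scaled by `1 + h·(1/φ − 1)`, so *h* = 1 restores the expected
EPSP exactly and *h* = 0 leaves release unchanged. Two identities follow and
anchor the tests: noise-free `EPSP = QC × q` exactly, and the percent QC
change under PhTx equals `(1/φ − 1)·h·100` (= 100 % at the defaults).

Defaults for a genotype: `q_mean` 0.5 mV, `qc_mean` 40, both CVs 0.2,
`meas_cv` 0.05, `mini_rate` 2 events/s. These sit in the range typical of
wild-type larval muscle-6 recordings (mEPSPs of a few tenths of a mV, QCs of
tens of vesicles) and give per-genotype estimates with realistic scatter at
n ≈ 10–30 NMJs per state.

What the simulator does **not** emulate: nonlinear summation of large
EPSPs, short-term depression during stimulus trains, per-NMJ coupling
between quantal size and release (the compensation responds to φ, not to the
NMJ's own realised *q*), and any morphological covariates. Passing tests
therefore demonstrate the *analysis machinery* is correct on data obeying
the declared model, not that the model captures every feature of real
recordings.

## Quantal metrics

`quantal_content` is the plain ratio of mean EPSP to mean mEPSP with no
nonlinear-summation correction. Percent QC change per genotype is computed
on the **ratio of genotype means** (mean +PhTx QC over mean −PhTx QC), the
robust default for small unpaired groups; a `mean_of_ratios` variant
(average of all pairwise +/− ratios) exists for sensitivity analysis and is
biased upward under baseline variability (Jensen). The PHP classification
bins are: change < 15 → *blocked*, 15 ≤ change < 30 → *suppressed*,
≥ 30 → *intact*; boundaries are assigned upward (15 is suppressed, 30 is
intact) and negative changes are blocked. The within-genotype test is a
two-tailed two-sample Student's t on per-NMJ QC (Welch behind a flag);
significance is reported alongside the class but never alters it.

`fit_mepsp_qc` regresses QC on mEPSP by OLS and reports r² as the squared
Pearson correlation. On recordings pooled across PhTx states, a compensating
genotype shows the inverse relation (small quanta, high release) and a
blocked genotype abolishes it.

## The screen decision procedure

Two criteria, each reported per genotype so calls are auditable:

1. **SD criterion** — the genotype's mean +PhTx QC is *strictly more than*
   one sample SD below the mean of all genotype means. The tested genotype
   is included in the population (no leave-one-out), and the population is
   the set of genotype means, not individual recordings. Note this
   criterion intentionally flags the lower tail of whatever population it
   is given: under a pure null it marks roughly the 16 % of genotypes that
   happen to fall one SD low. A near-zero null false-positive rate is a
   property of the envelope criterion and of the conjunctive combination,
   not of the disjunction.
2. **Envelope criterion** — an OLS centre line is fitted to the reference
   genotype's individual +PhTx (mEPSP, QC) recordings, and residual order
   statistics are trimmed symmetrically so that at most
   `floor(n·(1 − coverage))` fitting points fall outside; empirical coverage
   on the fitting data is therefore ≥ the target (default 0.95) by
   construction, for any target in (0, 1]. A genotype flags when its mean
   point falls **below the lower boundary** — the criterion is one-sided
   because PHP defects depress QC; this also makes hit calls monotone
   (lowering a genotype's QC can only create a hit, never remove one).

Criteria combine with OR by default (`rule="either"`); AND is available.
Candidate hits are triaged with −PhTx data: a two-tailed Student's t-test of
the candidate's baseline EPSP against the reference at α = 0.05 separates
`baseline_defect` from a selective `php_defect`; candidates without −PhTx
recordings come back `untested` with a warning. Planted-hit ground truth in
the simulator is `compensation < 0.5`, an arbitrary but declared and
configurable convention.

## Interaction matrix

Cells are keyed by `"{row};{col}"` genotype labels and populated with the
same per-genotype summary as above. Dunnett's many-to-one adjustment
against the wild-type cell is computed by seeded Monte Carlo: under the
global null the vector of comparisons is a correlated multivariate t
(shared control mean and pooled variance on N − k df), and the adjusted p of
a cell is the fraction of draws whose max |t| exceeds the observed |t|.
Default 10⁵ draws give ±0.002 resolution near p = 0.05; the implementation
agrees with closed-form multivariate-t evaluations to better than 0.01. No
omnibus ANOVA gate precedes the comparisons (a flagged design choice —
gating is ad hoc and costs power); the within-cell ±PhTx t-test remains the
authoritative statistic for PHP classification, with the Dunnett column
reported as the secondary, family-wise-controlled comparison.

## Count-data sub-module

The differential-expression test is deliberately simple and fully declared;
it is **not** a DESeq2/limma re-implementation:

- median-of-ratios size factors (geometric-mean reference over genes with
  all-positive counts; library-size ratios as fallback);
- per-gene NB dispersion by method of moments, pooled within
  genotype × batch groups, then **floored at a trended estimate** (median
  dispersion within 20 log-mean bins) and at 0.01. The trend floor stops
  genes whose few replicates happen to agree from borrowing an
  unrealistically small dispersion — the classic source of
  anti-conservative NB Wald tests at n ≈ 4;
- a log-linear NB model `count ~ genotype + batch` with `log(size factor)`
  offset, fitted by IRLS vectorised across all genes simultaneously;
- a two-sided Wald test on the genotype coefficient with a normal
  reference. With the trend floor this is empirically calibrated: the
  suite's 200-seed null calibration (1000 genes, 4 vs 4 samples in two
  batches, dispersion 0.05) checks the rejection rate at α = 0.05 against
  the [0.03, 0.07] band;
- log2 fold changes reported on size-factor-normalised group means with a
  0.5 pseudocount.

DEG calling uses FDR < 0.05 (strict, boundary fails) and fold change ≥ 1.5
or ≤ 2/3 (boundary passes). The CPM filter drops a gene only when it is
below threshold in *every* sample (boundary passes; all-zero genes always
drop). Exclusive intersections assign each DEG to the exact set of contrasts
calling it, so sizes always sum to the union. Synergy selection requires a
gene to be DE in the double mutant against wild type *and* both single
mutants with the same sign of log2fc in all three contrasts — the
direction-consistency requirement is a declared interpretation, since
"dysregulated against all controls" is ambiguous about sign. ΔΔCt fold
changes are `2^−(mean ΔCt(test) − mean ΔCt(control))`.

## Event detection

Minis are detected with a matched filter: cross-correlation of the trace
with the zero-meaned, L2-normalised difference-of-exponentials kernel
(rise 1 ms, decay 8 ms by default), thresholded at `threshold_sd` (default
3.5) times a robust noise SD (1.4826 × MAD of the score, immune to the
events themselves). Local maxima separated by the refractory interval
(5 ms) become events; candidates within ±100 ms of a stimulus are excluded,
and candidates whose baseline-to-peak amplitude is non-positive (template
matches inside downward noise dips) are discarded. Amplitude is peak minus
the median of the 10 ms before onset; event time is the onset, directly
comparable to planted ground-truth times. On effectively noise-free traces
the MAD floor switches to 10⁻⁴ of the largest score so numerical ripple
never fires. Evoked amplitudes are window maxima (50 ms) minus the
pre-stimulus baseline median, one per stimulus, with overlapping windows
rejected.

## Problem sizes and numerical choices

Simulation-based checks in the suite use the study-like defaults: 10–30
NMJs per genotype and state, 10–15 deficiency screens with 3 planted hits,
20-seed sensitivity/specificity replicates, 200-seed calibrations at 1000
genes, and a 300-seed Dunnett family-wise-error check at 2¹⁴ draws (the API
default stays at 10⁵ draws). IRLS runs at most 50 iterations to 10⁻⁸, with
linear predictors clipped at ±30 to avoid overflow; ties between candidate
event peaks break by filter score, then earlier time. All randomness flows
from explicit `numpy.random.Generator` streams; the pipeline derives child
streams per stage from one master `SeedSequence`, so identical
configurations give identical outputs.

## Known limitations

- The screen criteria inherit the statistical quirks of their definitions
  (see the SD-criterion tail note above); they reproduce a decision
  procedure, not an optimal detector.
- The NB test's fold changes are unshrunk; near-zero counts make them
  noisy. Numeric concordance with shrinkage-based tools on real data is
  out of scope.
- The mini detector does not deconvolve overlapping events or fit kinetic
  constants; heavily overlapping minis at high rates are undercounted.
- Percent-homeostasis estimates at n = 20–30 carry a sampling SD of about
  5–7 percentage points at the default CVs; single-seed values near a
  classification boundary should be interpreted accordingly.
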