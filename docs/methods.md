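# Methods

This note documents the models and procedures `cntbind` implements, the
parameter choices that matter, what the synthetic generators do and do not
emulate, and the numerical decisions taken where the design was open.

## The selection model

Real affinity selection binds a random oligonucleotide library to nanotubes,
discards unbound molecules and re-amplifies the bound ones.  The simulator
reduces one round to two steps:

1. **Boltzmann-weighted resampling.**  `n_draw` sequences are drawn with
   replacement with probability ∝ count·exp(score/T), where `score` is the
   ground-truth affinity of the insert and the temperature `T > 0` sets
   selection stringency (T → ∞ recovers plain multinomial resampling; the
   weights are computed with a max-shift so large scores cannot overflow).
2. **PCR noise.**  Each surviving count is multiplied by a mean-1 lognormal
   factor with coefficient of variation `pcr_cv` (default 0.2) and rounded.
   Amplification bias is multiplicative and heavy-tailed, which a lognormal
   captures with one parameter; sequences rounded to zero are lost, as in a
   real bottleneck.

The ground-truth **affinity model** is additive: per-base weights, per-dimer
weights (overlapping), and position-anchored 3-mer motif weights.  The motif
term makes affinity depend on base *order*, so composition-preserving
shuffles change the score — the property the scrambling experiments and the
ML shuffling ablation probe.  The convenience model used throughout favours
A/C over G/T at ±0.1 score units per base.

Two selection regimes appear in the examples and checks, chosen once as
study conditions: **T = 1** for enrichment profiling (strong, rapid
enrichment: the A+C share of the top-20,000 profile rises every round and
gains well over 5 points by round 6) and **T = 2** for the round-wise
machine-learning experiment, where softer selection keeps round 3
informative but unsaturated so the rise of prediction performance across
rounds is visible.  Library sizes of 50,000 unique inserts and 50,000 draws
per round keep a six-round run under a few seconds; these are desk-scale
stand-ins — a real round-0 library holds ~10^16 molecules, a scale no
desk simulation attempts to match.

## Displacement kinetics

The fluorescence peak of a DNA-wrapped nanotube blue-shifts as a surfactant
(sodium cholate) displaces the DNA.  The peak-wavelength trace is modelled
as first-order decay after the addition time:

λ(t) = λ∞ + (λ0 − λ∞)·exp(−(t − t_add)/τ),  t ≥ t_add.

`fit_time_constant` fits (λ0, λ∞, τ) by nonlinear least squares
(scipy `curve_fit`), initialised from the pre-addition mean (λ0), the tail
mean (λ∞) and a log-linear slope (τ).  Default trace geometry follows the
measurement protocol: 20-s sampling over ~600 s with addition at 100 s, peak
moving 1129 → 1115 nm.

**Censoring.**  A construct that shows no measurable shift within the
window is reported censored (INF) — the strongest binders.  The rule:
censored unless *both* the fitted amplitude |λ0 − λ∞| *and* the model-free
amplitude (pre-addition mean minus tail mean) reach `shift_min_nm = 1.0`.
A three-free-parameter exponential can manufacture a ≥1 nm "shift" out of
pure noise on a flat trace (a tiny τ fits a single early point); requiring
the model-free amplitude as well makes flat traces at instrument-level
noise (≤0.3 nm) censor in ≥95% of runs, while a true 14-nm shift passes
with huge margin.  1 nm sits at the noise scale of the traces described.

**Labeling.**  high-affinity ⇔ censored or τ ≥ 90 s.  The boundary value
itself labels high (the threshold wording does not fix the boundary; ≥ is
the choice here, recorded once in `label_affinity`).  The ML affinity
dataset pipes through this single function so the rule lives in one place.

Peak extraction refines the windowed argmax by 3-point parabolic
interpolation (exact for a locally quadratic peak on a uniform grid; an
edge maximum or flat top returns the grid point).  The Pearson correlation
between time constants and summed per-base dissociation enthalpies is
computed on the linear τ scale with censored values excluded upstream; the
per-base enthalpy table is a required user input (literature values, units
caller-defined).

## Trajectory statistics

Trajectories are bead-level (coarse-grained force fields map 2-4 heavy
atoms to one bead): roles `backbone`, `base`, `cnt`, with the nanotube an
infinite cylinder (radius 0.6 nm) along the z-axis of the box, bonded to
itself across the periodic boundary.  Distances therefore use the
minimum-image convention along z only; x/y are open.

* **H-bonds:** two nucleotides form a hydrogen bond in a frame when any
  base bead of one is within 0.35 nm (3.5 Å) of any base bead of the other.
  Nucleotides fewer than `min_seq_sep = 2` positions apart are excluded:
  chain neighbours are topologically bonded and would satisfy the distance
  rule trivially (set 0 to disable; same-nucleotide bead pairs are always
  excluded).  Pairs are canonicalised (i < j).
* **Near/far:** a bonded pair is *near* when the smaller of its two
  partners' surface distances (radial distance to the axis minus the
  radius, clamped at 0) is below 0.6 nm (6 Å), else *far* — the minimum is
  the conservative reading of "near".  Percentages are
  near/(near+far)·100 and far/(near+far)·100; with no bonds at all they
  are reported as undefined (None), never NaN.
* **Per-position means** average, over the analysis window (default the
  last 2,000 frames), the number of bonds each nucleotide participates in.
* **MSD:** the centre of mass of the selected beads (equal weights — bead
  masses are near-uniform at this resolution) is unwrapped along the
  periodic axis, then MSD(k) = ⟨|r(t+k) − r(t)|²⟩ is averaged over **all
  time origins** via the FFT autocorrelation decomposition (O(T log T)).
  A single-origin mode (|r(t) − r(0)|²) is provided; the two agree at the
  final lag.  The FFT estimator matches a direct double-loop evaluation to
  better than 1e-10 nm² on a 5,000-frame random walk.

The toy trajectory generator is a geometric fixture, not physics: a
single-turn helix of 30 nucleotides on the tube surface whose non-neighbour
base beads stay ≥0.8 nm apart, with requested pairs planted 0.25 nm apart
at a prescribed surface offset on the far side of the cylinder (a
construction check rejects layouts that would create ambiguous contacts).
It validates the *analysis statistics* — detection, classification,
averaging — and says nothing about force fields or real DNA conformations.

## Machine learning

**Encodings.**  k-mer vectors (4^k columns, lexicographic, overlapping
counts, optional frequency normalisation; row sums 31−k for 30-mers) for
the tabular models, 30×4 one-hot (column order A, C, G, T) for the sequence
models.  2-mer is the default k for RF/MLP (the best-performing k for
tabular models on this task).

**Families and defaults** (all overridable per `ModelSpec`): RF = 500
trees (scikit-learn); MLP = dense 128-64; CNN = five same-padded 1-D conv
layers (64 filters, kernel 5, ReLU) → global max pool → FC(64) → logit;
GRU = one layer, hidden 64, last-state readout; transformer = learned
positional embedding, two pre-norm encoder blocks (model dim 64, 4 heads),
mean pool.  The neural engine is an in-package numpy implementation with
hand-written backward passes, verified against central finite differences
in the test suite; optimisation is Adam (lr 1e-3, batch 64), binary
cross-entropy on logits, early stopping on validation AUC (patience 10, max
200 epochs).  Training is single-threaded and bit-deterministic under a
fixed seed; RF is deterministic via its random_state.  The one-hot input is
laid out positions-first, (length 30 × channels 4).

**Binding protocol.**  Positives = top-10,000 sequences by frequency
(configurable); negatives = uniform random 30-mers rejection-sampled
against the positive set (checked against positives only, not the whole
library).  Repeated (default 10×) random 60/20/20 train/val/test splits;
splits containing a single class are redrawn.  Metrics: accuracy,
AUC, precision, recall, F1 at probability threshold 0.5, with AUC computed
from the Mann-Whitney rank statistic (tie-aware; equal to the trapezoidal
ROC area, asserted against an independent implementation in tests).

**Transfer learning.**  The binding CNN's first `n_freeze = 3` conv layers
are frozen (their parameters are excluded from optimiser updates and
asserted bit-identical after fine-tuning); remaining layers fine-tune on
the affinity dataset under repeated stratified 4-fold CV with a fixed
epoch budget (no validation split is carved from 54-sequence training
folds).  Out-of-fold probabilities are pooled over all 72 sequences per
repeat to form the ROC.

**Shuffling ablation.**  Each test sequence is permuted in place (its
1-mer profile unchanged) and the model re-evaluated; the AUC drop measures
reliance on base order.  The p-value is a randomization test: the fraction
of shuffles scoring at least the original AUC.  With an order-dependent
(motif) ground truth the drop exceeds 0.05 by a wide margin; with a purely
compositional ground truth it is ~0.

**Candidate ranking** scores a pool and returns the top/bottom sequences
by probability with lexicographic tie-breaks, mirroring a
predict-then-validate design (e.g. 5 + 5 from 100,000 candidates).

## What the synthetic data does and does not show

The generators reproduce the *statistical structure* the analyses assume:
round-over-round compositional enrichment, order-dependent affinity,
exponential traces with censoring, planted near/far contacts, and an
affinity table whose class composition (20 high / 52 low of 72 at the 90-s
threshold) matches the measured dataset this pipeline is designed for.
Passing tests therefore demonstrate that each statistic and protocol
computes what it claims on data with known ground truth.  They do not
demonstrate sequencing-error robustness (no read-error model), thermodynamic
realism, chirality-resolved spectra (one tracked peak), or real secondary
structure — and metric values on synthetic data (e.g. transfer AUC ≈ 0.9)
characterise the synthetic task, not the laboratory one.

## Other numerical choices

* Ranking ties break lexicographically (ascending) so top-N boundaries are
  deterministic; ranking preserves the count multiset.
* Dimer and higher k-mer counting uses overlapping windows (the k-mer
  convention; 29 dimers per 30-mer).
* Insert extraction tolerates `max_mismatch = 1` Hamming mismatches per
  primer, tries the reverse complement when the given orientation fails,
  and rejects (with reason) inserts that are not exactly 30 nt or contain
  N.  Both anchor strings are configurable.
* k-mer profiles default to `by_unique` weighting (each unique sequence
  once, matching "top N sequences" profiling); `by_count` weighting is
  available.
* The acceptance script runs at reduced problem sizes (e.g. 1,500+1,500
  binding sequences, 200 traces, 5,000 frames, three selection replicates
  for the round-wise means) — sizes chosen so the whole recomputation
  completes in about a minute while every estimate stays well-resolved.
* `extract_peak_wavelength` assumes a locally uniform wavelength grid
  around the maximum.
* All randomness flows through per-call integer seeds; no global RNG state.

## Known limitations

* `score_sequence` is additive; epistatic interactions beyond anchored
  3-mers are not representable.
* The exponential fit assumes a single kinetic phase and a single tracked
  peak; multi-chirality deconvolution is out of scope.
* GRO/XTC trajectory ingestion is not built in; trajectories arrive via
  the TSV dialect (a bead-role mapping makes other sources easy to adapt).
* The numpy neural engine is CPU-only and sized for desk-scale datasets
  (10^3-10^4 sequences), which is exactly the regime of this pipeline.
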