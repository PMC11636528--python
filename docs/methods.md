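# Methods

`clozanet` reimplements a multimodal machine-learning analysis that asks
whether future treatment resistance (an indication for clozapine) can be
predicted at the first episode of psychosis from three data modalities:
clinical variables, grey-matter concentration maps (voxel-based
morphometry, VBM) and inter-subject correlation (ISC) maps from fMRI
recorded during naturalistic movie viewing. Because no such cohort is
publicly available, the package ships a synthetic-cohort generator with the
same statistical structure, and every result the package reports is
computed on synthetic data.

## Inter-subject correlation maps

For subject *s* and an independent reference group of subjects
*j = 1..N<sub>ref</sub>* who watched the same stimulus, the ISC map is, per
voxel *v*,

    z̄_s(v) = (1/N_ref) Σ_j artanh( r( x_s(v,·), x_j(v,·) ) )

where *r* is the Pearson correlation of the two voxel time courses and
artanh is the Fisher z-transform, applied before averaging because z is
approximately variance-stabilizing. Maps are kept in z space; no
back-transform is applied. Only subject-versus-reference pairs are
correlated, never reference-versus-reference pairs.

Numerical choices: correlations
are clamped to |r| ≤ 1 − 10⁻⁷ before artanh so that identical time courses
cannot produce infinities, and a voxel whose time course is constant (up to
floating-point residue of a constant level, sd ≤ 10⁻¹² · (|mean| + 1))
contributes r = 0 — such voxels occur at mask edges and carry no signal.

## Feature construction

Each imaging map is pooled over an integer-labelled parcellation (274
regions at full scale; the Brainnetome atlas plays this role for real
data): per region, the minimum, maximum, mean and standard deviation of its
voxels. SD is the sample standard deviation (n − 1); single-voxel regions
get SD 0. Two modalities × four statistics × 274 regions = 2192 imaging
features next to the 81 clinical variables.

Clinical preprocessing is refit inside every cross-validation run from that
run's training rows only: scalar/ordinal variables are imputed with the
training mean, binary/categorical with the training mode; a
nicotine-dependence score is imputed 0 for non-smokers (the score is
defined as 0 for anyone who does not smoke) before its mean is taken.
Categorical levels are integer-coded (one column per variable, preserving
the 81-input architecture); a level unseen in training maps to an extra
"unknown" code. Every clinical column is then min–max scaled with training
statistics, so training rows land in [0, 1] and test rows are clipped to
[0, 1]. A column constant in training scales to 0 (information-free).
Imaging features pass through unscaled: Fisher-z ISC values and grey-matter
concentrations are naturally order-1.

## The sparse multimodal network

The classifier is a feed-forward network of up to nine parallel
subnetworks, one per feature block (clinical + 8 pooled maps). Input *i*
of a block connects to its own ten dedicated first-hidden-layer nodes;
all of a block's first-layer nodes connect to that block's single
second-hidden-layer node; the second-layer nodes connect to one common
output node. Every node uses the logistic activation. There are no
connections across blocks before the output layer, so modalities with many
features cannot crowd out small ones, and each second-layer activation is
one modality's contribution. Only the structurally non-zero weights are
stored (compact (D, 10) arrays), so the zero pattern is invariant under
training by construction.

Training minimizes binary cross-entropy (the canonical pairing with a
logistic output) with ADAM:
learning rate 10⁻⁴, decay parameters 0.9/0.999, stabilizer 10⁻⁸, batch
size 10 drawn uniformly without replacement each iteration, 10 000
iterations in the full protocol ("iteration" = one mini-batch step).
Weights initialize uniformly in ±√(6/(fan_in + fan_out)) per connection
group; biases start at 0. Training is deterministic per seed. When a
(tiny, test-scale) training set is smaller than 10, the batch size is
clamped to the training-set size. The baseline comparator is a linear
soft-margin SVM with C = 1.

The hot training loop is a fused numba kernel; a unit test pins one full
training step to a reference gradient implementation, and the reference
gradients are themselves checked against central finite differences at
1e-5.

## Evaluation protocol

Randomized-pair cross-validation without resampling: each run holds out one
random subject per class, balances the training set by randomly omitting
majority-class subjects (7 vs 31 becomes 6 vs 6 training), refits the
clinical preprocessor on the training rows, retrains the model from
scratch, and scores the pair — per-run accuracy is 0, 50 or 100 %. The
full protocol uses 2000 runs. Reported are the mean per-run accuracy with
a 95 % percentile bootstrap CI over runs (10 000 resamples) and the
ensemble hard vote: each subject's final class is the majority prediction
over the runs in which it was tested, with ties resolved to the positive
class (missing a treatment-resistant patient is the costlier error).
Subjects never tested (possible at
very small run counts) are excluded from the voted confusion with a
warning; undefined confusion ratios are reported as not-available rather
than 0.

Significance of an accuracy is one-sided permutation inference: the
analysis is re-run under shuffled labels and p = (1 + k)/(1 + P) where k
counts permuted statistics ≥ the observed one; with P = 1000 the smallest
attainable p is 0.000999. Two analyses are compared two-sidedly by
shuffling per-run accuracies between them and ranking the absolute mean
difference, same add-one convention. At desk scale the number of CV runs
inside each permutation and the training length are configurable down;
defaults match the full protocol.

## LRP importance

Feature importance uses layer-wise relevance propagation with the
epsilon-stabilized proportional redistribution rule (ε = 10⁻⁶): the output
activation (for true class 1; its complement for class 0) is redistributed
layer by layer in proportion to each connection's contribution a·w to the
downstream pre-activation. With zero biases the rule conserves relevance
up to stabilizer leakage; a node whose pre-activation is exactly 0 absorbs
the relevance routed through it (its activation is pure offset), which is
the correct limit of the rule. Inputs with all-zero outgoing weights
receive exactly zero relevance. Per run, relevance is computed for both
test subjects toward their true class regardless of whether the prediction
was correct; sums over runs give per-variable importance per class, means
over regions give one importance per map, and each block's top-10 features
(top-k configurable for desk-scale tests) are ranked, with the per-modality
pooled region list being the union of that modality's four maps' top lists.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
the biology:

* **Shared stimulus drive.** Each atlas region has one latent time course
  drawn once per cohort (every viewer watches the same movie). A voxel
  time course is `a·c·s_r(t) + N(0,1)` with amplitude a = 1 and coupling
  c = 1, giving an expected subject–reference voxel correlation of 0.5 —
  deliberately stronger than typical naturalistic-fMRI ISC so that a
  12×12×12 desk-scale grid carries usable signal. Positive subjects'
  coupling is multiplied by a per-region attenuation in [0, 1]; reference
  subjects always couple fully.
* **Grey matter.** Region base levels U(0.3, 0.7), voxel noise sd 0.1,
  plus an additive per-region shift for positive subjects.
* **Clinical table.** 81 columns cycling scalar / ordinal / binary /
  categorical (≤ 6 levels, mirroring symptom-scale items without cloning
  any instrument), with standardized group mean shifts on designated
  columns, a smoker flag whose paired nicotine score exists only for
  smokers, and missingness planted completely at random within 27
  designated columns at 4.2 % of all table cells.
* **Dimensions.** 38 subjects, 7 positive, 44 references, 240 time points;
  20 regions by default for test speed, 274 available by configuration.

The planted-effects preset used by the signal-recovery tests and the
acceptance script attenuates ISC coupling to 0.25 in four regions, shifts
six scalar clinical variables by +1.2 SD and four regions' grey matter by
+0.15. What passing tests show is that the pipeline recovers planted
multimodal signal and stays at chance under the null — not that real
first-episode cohorts carry such signal; the generator makes no claim of
clinical realism (no instrument-specific distributions, no scanner
physics, no motion, no preprocessing artefacts, no correlated clinical
covariates).

## Problem sizes in the test suite and acceptance script

Full-protocol defaults (2000 runs, 10 000 iterations, 1000 permutations
each re-running the complete CV, 10 000 bootstrap resamples) are the
package defaults, but the shipped checks run a scaled-down protocol chosen
as desk-scale study conditions: null calibration uses 20 cohorts × 200
runs at 1000 iterations with 19 permutations of 8-run re-analyses; signal
recovery uses 100 runs at 3000 iterations with 50 permutations of 15-run
re-analyses; the acceptance script uses 200 runs, 3000 iterations and the
same permutation scale, with the bootstrap at the full 10 000. Bootstrap
and voting operate on whatever runs exist, unchanged.

## Known limitations

* At strongly reduced training (~1000 iterations) the network's two test
  scores move almost in lockstep (output-bias dominated), so under the
  null most runs score exactly 50 % — mean accuracy is honestly at chance
  but the per-run accuracy distribution is narrower than in the full
  protocol.
* The label-shuffled importance baseline inherits the planted features'
  inflated variance, so at desk scale planted regions remain salient even
  under shuffled labels; the importance-recovery test therefore compares
  the *magnitude* of the between-class relevance contrast (true labels vs
  shuffled), which separates cleanly.
* Permutation re-analyses use fewer CV runs than the observed analysis,
  inflating the permuted spread; the resulting p-values are conservative.
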