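# Methods

## Problem setting

An electronic nose measures an odor by exposing an array of
differently-coated nanomechanical sensor channels to a vapor and
recording each channel's stress-response trace over time. The analysis
implemented here asks two questions about such multichannel traces:

1. Can molecular properties of the odorant — its chemical category,
   whether it carries oxygen atoms (and how many), whether it contains
   a ring — be predicted from the signal array?
2. Which channels (receptor coatings) and which parts of the signal
   (adsorption vs desorption phase) drive those predictions?

Question 1 is answered with a small convolutional network evaluated by
leave-one-out cross-validation (LOOCV), with support-vector-machine and
random-forest baselines on hand-crafted kinetic features. Question 2
is answered with Score-CAM, a gradient-free class-activation-mapping
method, whose per-sample importance maps are aggregated per class and
summarized per channel.

Because the package is exercised on synthetic data, the simulator
plants known channel-property affinities, so that the explanation
pipeline can be scored against ground truth — something impossible
with real measurements.

## Signal model

Each trace follows first-order (Langmuir-like) adsorption/desorption
kinetics on a 20 Hz grid over 120 s: a 30 s exposure (sampling) phase
and a 90 s nitrogen purge:

    S(t) = A_eff (1 - e^(-t/tau_ads))                      0 <= t <= 30 s
    S(t) = S(30) (r + (1 - r) e^(-(t-30)/tau_des))         30 < t <= 120 s

* `A_eff` — effective amplitude (arbitrary units): a per-(channel,
  category) base amplitude times a concentration gain times molecular
  boosts (oxygen, ring).
* `tau_ads`, `tau_des` — adsorption/desorption time constants (s),
  drawn per (channel, category) from 5–15 s and 10–40 s.
* `r` (residual fraction, 0–1) — the part of the end-of-adsorption
  signal that never purges off.

No diffusion term, drift, or baseline wander is modeled; noise is
i.i.d. Gaussian per raw point (default sd 0.02, small relative to the
0.3–2.4 amplitude range). Signals are nonnegative in the noiseless
limit. Concentration gains default to (0.25, 0.5, 1.0) for (5, 10,
20)% — monotone and saturating, so the 20% plane carries each channel's
maximum in the noiseless limit.

### Planted ground truth

The default `AffinityModel` plants the following structure, recorded in
every dataset manifest:

* **Category signatures.** Each of the nine categories has one
  signature channel (esters -> 3, acids -> 14, aromatic
  hydrocarbons -> 2, halogenated compounds -> 4, alcohols -> 1,
  ethers -> 5, others -> 10, aliphatic hydrocarbons -> 11,
  ketones -> 12) carrying a 3x amplitude boost **and** a signature
  kinetic shape (tau_ads = 1.5 s, residual 0.7). The shape component is
  essential: the CNN input normalizes every channel by its own maximum,
  which erases pure amplitude differences, so a planted effect must
  change the trace *shape* to be visible to the network. The amplitude
  component is still meaningful for the raw-scale kinetic features the
  SVM/RF baselines consume.
* **Acids** additionally get residual 0.8 and tau_des = 60 s on channel
  14 (slow desorption — acids remain in the receptor layer), and
  **alcohols** get tau_ads of 1.5–3 s everywhere (fast adsorption).
* **Oxygen.** Molecules with n oxygen atoms get, on channel 4, an
  amplitude factor 1 + 0.6n and a residual shift +0.3n (hydrogen
  bonding retains the molecule), with weaker shifts (+0.1n) on channels
  2 and 3. The per-atom scaling makes the 0/1/2 oxygen-count classes
  separable, not just oxygen presence.
* **Ring.** Ring-bearing molecules get a 2x amplitude factor and a
  +0.4 residual shift on channel 2 (pi-pi stacking against the
  styrene-type coating) and a weak secondary response (+0.2) on
  channel 13.
* Channels 8 and 9 share base kinetics up to a +0.05 amplitude offset
  (same receptor material, different coating method); no structure is
  planted on them, so a correct analysis should rank them unimportant.

Effective residuals are clipped to [0, 0.95]. Category label profiles
(oxygen-count distribution, ring probability per category) mirror a
pure-solvent panel: acids/esters carry two oxygens, alcohols/ethers/
ketones mostly one, hydrocarbons none, aromatics always cyclic.

What the generator does **not** emulate: real receptor cross-
sensitivities, humidity/temperature effects, drift, negative-going
responses, and solvent-specific chemistry. Passing the planted-recovery
tests therefore shows the *pipeline* can recover affinities that exist
in the data; it says nothing about which affinities exist in real
measurements.

### Seeding

One master seed drives a dataset. Label assignment uses one derived
stream; every (sample, channel, concentration) trace gets its own
`SeedSequence`-derived noise stream, so datasets are bitwise
reproducible and insensitive to generation order.

## Preprocessing

* The value at t = 0 s is subtracted from every trace.
* Points are taken every 3 s, giving 40 points at t = 3, 6, ..., 120 s.
  The grid excludes t = 0 (identically zero after baselining) rather
  than t = 120; both readings give 40 points, this one keeps the purge
  end.
* Each channel's 40 x 3 block is divided by its single maximum over the
  three concentration planes, so each responsive channel attains 1.
  Channels with non-positive maxima are passed through unscaled and
  logged. Division is by the maximum value, not the maximum absolute
  value.

The baseline feature vector is 4 features x 14 channels x 3
concentrations = 168 dimensions, on the *unnormalized* (baseline-zeroed)
scale: end-of-adsorption level S(30), initial adsorption slope
(S(6) - S(3))/3, initial desorption slope (S(33) - S(30))/3, and the
post-purge residual S(120). Layout is concentration-major, then
channel, then feature — fixed so that random-forest importances can be
reshaped to (3, 14, 4) and averaged over concentrations and features to
give per-channel importances.

## Classifiers

The CNN is implemented directly in NumPy: it is small enough (about
75k parameters) that a framework is unnecessary, and a single-threaded
NumPy implementation is bitwise-deterministic given its seed, which
makes LOOCV folds and explanation outputs exactly reproducible.
Architecture: two 3x3 'same' conv blocks (8 then 16 filters, ReLU),
each followed by 2x1 max-pooling over time, flatten, dense 32 (ReLU,
optional inverted dropout, default 0), softmax output. The post-ReLU
output of the second conv layer — sixteen 20 x 14 activation maps — is
the Score-CAM interface. Training: Adam (lr 1e-3), cross-entropy,
30 epochs, batch 8. These defaults live in `CnnConfig` and are
overridable; the 16-filter final block is enforced.

Four tasks are defined on the molecule labels: the nine categories,
oxygen presence, oxygen count (0/1/2), and ring presence. Evaluation
is LOOCV throughout: each fold retrains from scratch with a
fold-derived seed and predicts its held-out sample; accuracy, macro F1
(per-class F1 with zero denominators counted as 0) and the confusion
matrix are assembled from the n held-out predictions. The SVM (RBF
kernel) and random forest run at scikit-learn defaults on the 168-dim
features. The RF channel-importance vector is taken from one forest
fit on the full dataset (fold-wise forests give near-identical
vectors, and the full-data fit is the natural analog of a single
reported importance profile).

## Score-CAM

For one input X and target class c:

1. extract the K = 16 final-conv activation maps;
2. bilinearly upsample each to the 40 x 14 input grid (corner-aligned,
   so constant maps stay constant) and min-max normalize (constant maps
   become zeros) -> masks H_k in [0,1];
3. score each masked input X * H_k (the mask is broadcast over the
   three concentration planes) and take the target-class probability
   s_k;
4. weight alpha = softmax(s_1..s_K);
5. combine L = max(0, sum_k alpha_k H_k) and min-max normalize.

Exactly K + 1 forward passes per explanation. Choices made where the
formulation is genuinely open: scores are post-softmax probabilities
(pre-softmax logits behind a flag); the increase-of-confidence variant
(subtracting the unmasked input's score before the softmax) is a flag,
default off; the combination sums the *upsampled normalized* maps so
the output lives on the input grid.

Each sample is explained with respect to its *predicted* class by the
LOOCV fold model that held it out — the explanation describes the
prediction actually made, by a model that never saw the sample.

## Aggregation and consistency

Class-averaged maps are the elementwise mean over samples with
true = predicted = class; individual maps are already in [0,1] and the
average is not re-stretched, so map intensity remains comparable across
classes. Classes with no correctly predicted samples yield an absent
map, never a zero-filled one. For the binary tasks the averaging
condition uses the binary task label (the natural reading for a
task-specific explanation).

Channel activity is the time-mean of an averaged map per channel,
normalized to unit sum (time-mean rather than time-max: robust to
single-point noise and matches the banded structure of averaged maps).
A per-task activity vector is the n-weighted mean of the class
activities, which equals the channel activity of the mean map over all
correctly predicted samples of that task.

The consistency summary reports (a) for each planted label, the rank of
its planted channel in the corresponding Score-CAM activity vector and
whether it is in the top 2, and (b) the Spearman rank correlation
between Score-CAM task activity and RF channel importance per task.

## Numerical and scope notes

* Max-pool gradient ties break toward the earlier time point.
* Min-max normalization maps constant inputs to zeros (not 0.5); an
  identically-zero combined map stays zero, so importance maps satisfy
  "max = 1 unless identically 0".
* A uniformly-zero averaged map yields uniform channel activity (1/14):
  it carries no ranking information.
* LOOCV folds whose training set lacks a class are run and logged, not
  skipped.
* Problem sizes: the standard study uses 9 x 5 = 45 samples; the
  acceptance reproduction runs the four tasks at this size, and the
  stochastic acceptance properties use seeds 1–5 at the same size.
* Out of scope: fitting kinetic parameters to real measurements,
  Grad-CAM/Eigen-CAM/Ablation-CAM, hyperparameter search, humidity or
  drift modeling, and any automatic retrieval of the deposited real
  dataset (an adapter contract documents the CSV layout it would need).

## Known limitations

* The permutation-null and recovery properties are stochastic; they are
  tested over multiple seeds with the tolerances stated in the tests,
  not as certainties.
* Score-CAM's softmax weighting over probabilities in [0,1] is
  low-contrast (weight ratio at most e); with only 1–3 genuinely
  discriminative channels the min-max-normalized masks give every
  channel a nonzero activity floor, so rank correlations with RF
  importances — which are near-zero off the planted channels — are
  positive but modest. The top-ranked channels, which carry the
  scientific conclusion, agree robustly.
* The CNN training-loss decrease contract is asserted on separable
  data; it is not a theorem for arbitrary data/hyperparameters.
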