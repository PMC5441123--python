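# Methods

`mibci` implements a hybrid motor-imagery (MI) brain-computer interface as a
set of testable components: a synthetic EEG/EOG generator, preprocessing and
characteristic-component selection, temporal-structure-preserving ICA,
one-versus-rest CSP feature extraction, a small-world neural-network (SWNN)
decoder with gray-code/idle output, and a finite-state shared-control layer
driving a headless 3D Tetris engine. This note records the models, the
defaults and why they were chosen, the numerical decisions, and the known
limits of what the synthetic evaluation can show.

## Synthetic recordings

The generator produces the data the pipeline assumes, so that every stage is
testable without recorded EEG.

**Source model.** M latent sources follow stationary univariate AR(P)
processes, S_t^i = Σ_{k=1..P} a_k^i S_{t−k}^i + φ_t^i, with independent
innovations. Class-dependent band-power modulation is generated by
multiplying the innovation scale of source i by a gain g(c, i) during a class
c MI epoch: epoch band power scales with g², so g = 0.5 is a 75 % power
suppression (ERD) and g = 1.5 a 125 % increase (ERS). Stability is enforced
by checking the AR characteristic roots; unstable models are refused with the
offending roots listed.

**Default "player1" profile** (M = 8, P = 6): six narrowband resonant
sources (AR(2) poles at radius 0.97) at sensorimotor/frontal sites with
physiologically signed gains — Cz 8–12 Hz (foot ERD 0.5, tongue ERS 1.5),
C3 12–16 Hz (right-hand ERD 0.5), C4 12–16 Hz (left-hand ERD 0.5),
Fz 14–16 Hz (tongue ERS 1.4), F4 20–22 Hz (right-hand ERS 1.3),
T7 24–26 Hz (left-hand ERS 1.2) — plus an unmodulated posterior alpha source
and a broadband heavy-tailed (Laplace) background standing in for non-neural
activity. Innovation scales (1.2–6 µV) give scalp amplitudes in the usual
tens-of-µV range. Hand imagery suppresses the *contralateral* central
source; tongue imagery only synchronizes, mirroring the ERS-only signature
reported for tongue MI.

**Forward model and artifacts.** Each source projects onto the 25-electrode
10-20 montage through a Gaussian spatial-leakage kernel centered at its
electrode (length scale 1.6 grid units); the broadband background mixes into
all channels with random smooth weights. The rendered recording adds a 50 Hz
sinusoid (5 µV, random phase per channel), white sensor noise (2 µV), and eye
blinks: a 300 ms biphasic pulse of 150 µV on the vertical EOG pair (inverted
at 0.8 gain on the lower electrode), with 30 % leakage onto the fronto-polar
channels; a double blink is two pulses 400 ms apart; default rate 6/min with
30 % doubles. A simulated reference-channel signal is subtracted from all
EEG channels, so stored data is already referenced. Ground-truth blink times
and kinds are kept on the `Recording` for detector scoring.

**Trial schedule.** The cue-paced protocol: 2 s blank, 4 s MI, four classes
each appearing 15 times per run in seeded random order, 2 runs per session,
2 sessions — 240 trials, 60 per class. Inter-run gap 10 s. All schedule
randomness is seeded and balance holds for any (sessions, runs, reps)
configuration.

**What the generator does not emulate:** volume conduction through a head
model, nonstationary drifts, EMG/electrode artifacts beyond blinks and line
noise, session-to-session covariance shift, or subject learning. Passing
tests therefore demonstrate correctness of the algorithms under the model's
assumptions, not performance on real EEG.

## Container

Recordings are stored as 16-bit EDF plus a JSON sidecar (schedule, blink
truth, montage extras). The EDF writer is a compact in-package
implementation of the format; files are read back through `mne`, which acts
as an independent implementation of the reader side. Round-trip error is
bounded by the per-channel quantization step, (phys_max − phys_min)/65535.

## Preprocessing

* **Notch**: zero-phase IIR notch at 50 Hz, Q = 40 — center attenuation
  ≥ 30 dB after forward–backward application while the ripple outside
  ±2 Hz stays under 1 dB. Residual output on a pure line tone is edge
  ringing only and vanishes with recording length.
* **Ocular correction**: ordinary least squares of each EEG channel on the
  EOG channels, residuals kept; EOG channels pass through untouched so blink
  detection still sees them. This is a deliberately transparent method;
  all-zero EOG degrades to a warned no-op.
* **Epochs**: [0, 4] s after cue onset, baseline-corrected by the mean of
  the 0.5 s preceding the cue, then CAR over the 25 EEG channels only
  (never EOG). Idle epochs are cut from the inter-trial blanks (shrunk
  0.1 s on both sides) — the idle baseline that the cue-paced protocol
  otherwise lacks.
* **Filterbank**: Chebyshev type-I bandpass designs, 0.5 dB passband
  ripple, applied as second-order sections forward–backward. `order = 10`
  is the final bandpass order (the scipy design order is half that). Bands
  tile 0–60 Hz in 2 Hz steps, the lowest edge clamped to 0.5 Hz to keep the
  design realizable; 25 channels × 30 bands = 750 components.

## Characteristic-component selection

Each (electrode, band) component is scored by the squared point-biserial
correlation between per-epoch band power and the binary task label — the
standard r² feature measure in sensorimotor-rhythm BCI — averaged over the
six class pairs (one-versus-rest contrasts are available as a config
alternative). The top 10 are kept, then screened for ERD/ERS plausibility:
a component passes if, for at least one class, its mean epoch power moves
against the idle baseline in the physiologically expected direction
(decrease for hand/foot, increase accepted for tongue). Ties break by lower
band, then electrode name; if screening would drop everything the top-1 is
kept with a warning.

## Temporal ICA

Sample-wise ICA ignores EEG's temporal dependence. Here the estimated
sources are modeled by a stationary autoregression and the independence
criterion is applied to the AR *residuals*: minimize an Infomax-style
negative log-likelihood, J(W) = −log|det W| + (1/T) Σ_t Σ_i log cosh e_i(t),
by natural-gradient descent, where e_i are the residuals of component i's AR
model and the score function tanh is backpropagated through each component's
AR filter (the update reduces to the classic (I − φ(E)Eᵀ/T)W at P = 0).

Two estimation decisions matter:

* **Diagonal AR inside the unmixing loop.** The generative assumption is
  that *sources* are independent, so cross-source lag coefficients vanish.
  Leaving the full multivariate AR free would let it whiten any invertible
  remixing of the sources (the residuals of Q·S are Q·Φ), collapsing the
  method to sample-wise Infomax on innovations — which cannot separate
  Gaussian sources. With per-component AR the temporal structure stays
  informative, and mixtures of Gaussian AR sources with distinct spectra
  separate cleanly (median Amari index well under 0.15 where sample-wise
  FastICA stays above 0.3). The full MVAR remains available as `fit_mvar`
  and via `diagonal_ar=False`.
* **Monotone acceptance.** Steps are accepted only if the objective does
  not increase; after rejections the rate halves and the search restarts
  from the best W, failing with the history attached if the rate collapses.
  Defaults: P = 6, lr = 0.05 (with backtracking), tol = 1e-6 relative,
  max_iter = 500, AR refit every outer iteration.

Whitening is PCA to full numerical rank (relative eigenvalue floor 1e-9); an
optional `whiten_var` truncates to the leading directions explaining a given
variance fraction, turning the transform into a denoising projection — off
by default because class information in ERD data lives precisely in
low-variance directions (measured: truncation at 0.99 costs several points
of downstream accuracy). The scale/permutation/sign indeterminacies are
fixed canonically: rows scaled to unit residual variance, ordered by
component power descending, sign set so each component's largest-magnitude
mixing entry is positive. This makes downstream spatial filters
reproducible bit-for-bit under a fixed seed.

The dependence diagnostic `residual_mutual_information` combines the
Gaussian mutual information of the residual correlation matrix
(−½ log det R) with a marginal log-cosh non-Gaussianity surrogate; it is
zero (up to sampling error) exactly for uncorrelated jointly Gaussian
residuals and grows with either correlation or marginal non-Gaussianity.

## One-versus-rest CSP

For each class c, with trace-normalized spatial covariances
Σ̂_c = mean_e(X_e X_eᵀ / tr X_e X_eᵀ) and Σ̂_rest the unweighted mean of the
other three classes, the filters solve the generalized eigenproblem
Σ̂_c f = λ (Σ̂_c + Σ̂_rest) f. This composite makes the paired eigenvalues
sum to one exactly (λ_c + λ_rest = 1, verified to 1e-8); the alternative
Σ̂_c vs Σ̂_rest composite is a config option. Eigenvectors follow the
f ᵀ(Σ̂_c + Σ̂_rest)f = 1 normalization; each filter's largest-magnitude entry
is made positive. The first and last n_pairs = 2 filters per class are
retained, features are log trace-normalized projection variances — 4 classes
× 4 filters = 16 features per epoch. Singular composites fall back to a
γ = 1e-6 identity shrinkage with a warning; zero-variance projections floor
at log 1e-12, flagged.

`first_last_gap` — the mean difference between first- and last-filter
projection variances in raw units — is the quantity used to compare the two
input pathways (direct band components, `cspW_Data`, versus ICA components,
`cspW_IC`).

### What the pathway comparison can and cannot show

The unit-residual-variance scaling of ICA components places them on an O(1)
scale while raw band components live on a µV² scale, so the raw-unit
first–last gap is systematically larger through the ICA pathway — the
ordering the comparison is designed to exhibit.

Cross-validated *accuracy*, however, is close to invariant between the two
pathways on this generator, and the package treats that as a finding rather
than a defect: the CSP generalized eigenproblem is covariant under any
invertible linear transform applied consistently to training and test data,
so a square unmixing changes the features only through per-epoch
trace-normalization weights. Measured across seeds the accuracy difference
is a coin flip (and dimension-reducing variants — PCA truncation,
discriminability screening of components — measurably hurt, because class
information sits in low-variance directions and in per-class
cross-correlations). A genuine accuracy advantage for the ICA pathway would
require data whose artifact structure breaks this symmetry (e.g. strongly
nonstationary artifacts), which the generator deliberately does not emulate.

## SWNN classifier

A feedforward network with 10 hidden layers of 8 tanh neurons between the
feature input and a 4-unit sigmoid output layer. Topology: start fully
layer-connected, then rewire each edge with probability 0.1 to a random
forward neuron (layer skips allowed), keeping at least one inbound and one
outbound connection per hidden neuron. Rewiring measurably shortens the
characteristic path length — the small-world signature.

Training minimizes per-bit cross-entropy between the sigmoid outputs and the
class codes (0001 right hand, 0010 left hand, 0100 foot, 1000 tongue) with
full-batch Adam (lr 0.01, 300 epochs default); every 50 epochs the weakest
5 % of active connections (by |w|) are cut and rewired to fresh random
forward pairs — the cut-and-rewire weight-adjustment move. The hard-limit
(0.5 threshold) output is inference-only, since it has zero gradient: the
four class codes decode to their classes and the remaining twelve 4-bit
patterns decode to the idle state, giving idle detection without idle
training data. Non-finite losses halve the rate and retry, aborting with
history after three failures. Same data + seed reproduces identical
weights.

## Shared control and the game

The control automaton has eight states {Start, N_B, Vc+ΔVx, Vc−ΔVx, Vc+ΔVy,
Vc−ΔVy, Vc = 0, Reset} over the eleven-symbol alphabet {left, right, ton,
foot, P=, P+, P− && Vc>0, Touch, Fallen, Cross, Null}. The transition table
is total: cells the published table leaves empty are self-loops, Start and
Vc = 0 share a column, Touch forces Vc = 0 from every state and Cross forces
Reset from every state; Reset ends the run before anything can leave it.
Speed semantics: entering a V± state on a directional symbol (or P+) adds
one ΔV increment (1 cell/s) along that axis; P− && Vc>0 removes one without
reversing; Vc = 0 zeroes the speed. Displacement accumulates continuously
and quantizes to one-cell moves (`control.mode = step` preserves the simpler
one-command-one-cell reading). Class-to-direction: foot → +y, tongue → −y,
left hand → +x, right hand → −x; idle carries no command.

Engine defaults: 6 × 6 footprint × 20 vertical layers, fall rate 0.5
layers/s, eight polycube shapes. Filling a layer clears it, scores one
unit, and drops everything above; landing with the topmost occupied layer
not full costs one remaining layer (the layer-attrition reading of the
stacking rule; `layer_loss="none"` disables it); a block protruding past the
remaining layers, or losing the final layer, emits Cross and ends the run.
The shadow is the vertical projection of the active block onto the current
stack, recomputed each tick, and equals the landing position absent further
commands (checked by rollout).

Blink commands: the vertical EOG is band-passed 0.5–15 Hz; peaks above 4
robust standard deviations (Gaussian-scaled MAD) with a 200 ms refractory
gap are blink events; two peaks within 600 ms merge into a double. A double
blink advances the rotation axis in the X→Y→Z loop; a single blink rotates
the active block 90° about the current axis, with colliding rotations as
logged no-ops. On the generator's defaults the detector scores ≥ 95 %
sensitivity at ≤ 1 false alarm/min.

Online decoding slides a 1 s window with a 0.25 s hop; each window's decoded
class emits its directional symbol plus a P symbol from the change in the
label's count over the last second versus the second before (idle emits
Null). The observed command rate is an outcome of this cadence, not a
parameter.

## Evaluation design and problem sizes

The cross-validation utility runs repeated stratified k-fold (10 × 10-fold
by default) with shared fold plans across pathways and classifiers, so
per-fold records are paired for significance testing. The classifier roster
pairs the SWNN with a same-size MLP, an RBF-kernel SVM, and an RBF
kernel-ridge least-squares classifier.

The packaged benchmarks (`mibci.benchmarks`) run scaled-down study
conditions chosen to keep the full evaluation minutes-long on one CPU while
preserving the protocol's structure: 250 Hz sampling, 1 session × 2 runs ×
10 reps (80 trials, 20 per class), a 4–32 Hz mu/beta filterbank, ICA capped
at 200 iterations on 80 k samples, and 2 × 4-fold CV with a 200-epoch SWNN.
The chance-level analysis uses the full 240-trial count and averages over
three label permutations; it uses the forced-choice kernel classifier
because the SWNN's idle codes push its null accuracy *below* 25 %.
Source-separation benchmarks use 3 sources at T = 20 000: resonant AR(2)
(order-4 fits) with Laplace innovations for the heavy-tailed case, and
broad AR(1) spectra (poles 0.3/0.6/0.85) with Gaussian innovations for the
spectra-only case.

## Known limitations

* The generator's stationary, artifact-light world means absolute decoding
  accuracies (mid-50s to high-70s percent across seeds) characterize the
  pipeline, not any real participant population.
* The pathway accuracy comparison is structurally near-tied here (see the
  CSP invariance note above); only the feature-gap ordering is a robust
  synthetic signature.
* The SWNN trains through a sigmoid surrogate; its hard-limit outputs are
  not calibrated probabilities, and idle detection has no tunable
  false-positive/false-negative trade-off beyond the 0.5 threshold.
* EDF storage quantizes to 16 bits of the per-channel range; sub-quantum
  waveform detail does not survive a round trip.
* The blink detector assumes the generator's template morphology; real EOG
  (saccades, slow drifts) would need threshold retuning.
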