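# Methods

This note records the modeling choices behind `chimerapred`: what the
synthetic generator emulates, how each pipeline stage is defined, which
parameters matter, and where the design was genuinely open.

## 1. Oscillator model and generator

**Dynamics.** Phases follow the Kuramoto–Sakaguchi equations
`dθᵢ/dt = ωᵢ + (1/C) Σⱼ K_ij sin(θⱼ − θᵢ − α)` with a two-population
coupling matrix: `K_ij = K` within a community, `r·K` across
(`r = 0.7` by default). The mean-field `1/C` normalization keeps `K`
comparable across channel counts. Integration is classical RK4 at
`dt = 1/sampling_rate` (numba-accelerated, NumPy fallback); a halving
of `dt` changes final phases by `< 1e-4 rad`, and all randomness flows
through explicit integer seeds.

**Why two populations.** A stable regime with one synchronized and one
incoherent group generally needs structured coupling; the two-community
topology reproduces that phenomenology while keeping the mean-field
form exact within a community.

**Frequencies, and a feasibility constraint.** The chimera-state
operating point places the synchronized community at 2.3 Hz (delta) and
the desynchronized one at 9.1 ± 1.3 Hz (alpha). With the `1/C`
normalization the maximal intra-community pull is
`K·n₀/C ≈ 0.37 rad/s`, so a within-community frequency dispersion of
order 0.5 Hz (≈ 3 rad/s) can never lock. The generator therefore treats
the synchronized community as near-identical oscillators (within-
community dispersion 0.01 Hz — the idealization under which partial
synchronization is classically analyzed) and reads the population-level
±0.5 Hz as across-recording variability. The desynchronized community
keeps its 1.3 Hz spread, which by the same arithmetic guarantees
incoherence. At the defaults this yields community order parameters
R₀ ≈ 0.99 and R₁ ≈ 0.30.

**Episode schedule.** Six segments with piecewise-linear parameter
ramps:

| segment | coupling | frequencies |
|---|---|---|
| baseline | 0.05 | all channels in the wide alpha band |
| emergence | 0.05 → 0.71 | community 0 slides to tight delta |
| stabilization | 0.71 | chimera operating point |
| transition | 0.71 → 1.2 | community 1 slides to delta |
| ictal | 1.2 | all near one delta frequency |
| postictal | 1.2 → 0.05 | relax back to baseline |

Two of these choices deserve emphasis. First, *ictal global synchrony
cannot come from coupling alone*: locking the alpha community's 1.3 Hz
spread would need `K ≈ 17`, far outside the admissible range, so the
seizure is modeled as pathological slowing — every channel's frequency
collapses toward the delta value while coupling rises, which is also
what the learned-parameter interpretation suggests (synchronized
components at delta during seizures). Second, *the interictal baseline
must be spectrally distinct, not just unaligned*: if the synchronized
community kept its near-identical delta frequencies during baseline,
5-second PLV windows would report near-unit locking (constant phase
differences within a window) even though the phases are dispersed, and
baseline would be indistinguishable from chimera to the entire PLV
pipeline. Placing baseline activity in the wide alpha band — the normal
awake rhythm, with the pathological delta group developing during
emergence and relaxing post-ictally — makes the generator's states
separable by exactly the features the method uses.

**Labels.** Ground truth comes from the simulated phases: per 5-s
window (50 % overlap), the true-community order parameters, the
contrast rule `max(R) − min(R) > 0.3` for the chimera flag (strict,
with a 1e-12 representation-error guard), segment membership for the
4-class state (0 baseline, 1 pre-ictal, 2 ictal, 3 post-ictal), and
minutes-to-onset capped at 90 for the regression target (ictal windows
carry 0; windows are timed on the uncompressed scale). Segment
durations are given in uncompressed real-time seconds; `time_compression`
(default 10) maps them to simulated time so a multi-hour progression
fits desk compute. The default layout (30/25/55/8/2/30 minutes) makes
the pre-ictal phases sum to 88 minutes, so baseline windows sit beyond
the 90-minute horizon. Post-ictal windows can legitimately carry a
chimera flag early in the segment: the delta group stays locked for a
while as coupling decays.

**Observation model.** `x_c(t) = A·sin(θ_c(t)) + ε`,
`ε ~ N(0, 0.1)`. The analytic phase of a sine carrier is `θ − π/2`;
this constant cancels in PLV, order parameters and instantaneous
frequency, and is accounted for in the round-trip test. The generator
makes no attempt at realistic EEG spectra (no 1/f background, no
spindles): it targets the phase structure the method consumes, so
passing tests demonstrate correctness of the machinery, not performance
on clinical EEG.

## 2. Parameter recovery

`estimate_kuramoto_params` regresses central-difference phase
derivatives on the mean-field regressors using
`sin(Δ − α) = sinΔ cosα − cosΔ sinα`, so the fit is linear in
`(ωᵢ, K cosα, K sinα)`; per-oscillator intercepts are profiled out
analytically. Rank-deficient designs (fully locked identical phases)
are flagged unidentifiable rather than returned; below `K̂ = 0.05` the
phase lag is flagged unidentifiable. The estimator is exact to
finite-difference truncation on mean-field (`r = 1`) trajectories;
under the two-community default (`r = 0.7`) the pooled mean-field
regression is misspecified and `K̂` is biased low (≈ 0.52 vs 0.71), so
the calibration benchmark runs recovery on the mean-field topology
where the regression matches the simulated dynamics. With 0.05-rad
phase noise, 60-s recordings and 20 seeds the mean estimates are
K̂ ≈ 0.705 and α̂ ≈ 0.279.

## 3. Preprocessing

Fixed order: polyphase resampling to 256 Hz (Hamming window) →
zero-phase 4th-order Butterworth bandpass 1–50 Hz (the forward-backward
pass doubles attenuation; at these corners the 60 Hz rejection is
19.0 dB by the squared magnitude response) → FastICA (scikit-learn; 20
components, seed 42, tol 1e-4, max 200 iterations) with five bespoke
artifact criteria → channel-wise z-scoring from interictal statistics
only. "Kurtosis" is the plain fourth standardized moment (Gaussian 3,
sinusoid 1.5), making the 5.0 threshold meaningful for heavy-tailed
blink components; the HF power ratio integrates a Welch periodogram
(2-s segments, 50 % overlap) above 30 Hz; all inequalities are strict
as printed. Flagged components are zeroed and remixed before the
interictal mask is applied (the alternative order is defensible; this
one keeps the pipeline strictly sequential). For synthetic data the
interictal mask is the baseline segment.

## 4. Phases, PLV, hypergraphs, chimera index

Hilbert phases carry a 0.5-s edge guard excluded downstream. PLV is the
modulus of the window-mean unit phasor of the phase difference,
computed on raw in-window samples (within-window autocorrelation biases
PLV upward identically for all methods; documented, not corrected).
Windows are half-open `[start, start+5 s)` with 2.5-s hop, 0-based.

Channel features are 9-dimensional (mean, variance, skewness; five
canonical band-power fractions; spectral Shannon entropy of the Welch
periodogram — sample entropy was rejected for cost). The adjacency
refiner multiplies MLP attention elementwise with PLV, row-softmaxes,
symmetrizes and max-normalizes back to [0, 1] — without that
renormalization a row softmax over 23 entries caps values near 1/23 and
the printed clique threshold τ = 0.65 would be meaningless. Identity
mode bypasses the refiner entirely (PLV pass-through), trivially
preserving the ranking contract; the pipeline uses identity mode by
default because the discrete clique step blocks gradients, so "joint"
refiner training cannot inform construction end-to-end.

Hyperedges are exactly the triplets whose three pairwise entries
strictly exceed τ; enumeration is exhaustive and verified against
brute force and an independent clique library. At the chimera operating
point the density is ≈ 12 % of C(23,3), inside the 10–30 % operating
range.

Chimera labeling uses spectral clustering (normalized Laplacian,
bottom-k eigenvectors, seeded k-means) with `k = 2` — the structure
loss speaks of most- and least-synchronized communities, and the
generator has two populations; `k` is exposed. The windowed chimera
index re-clusters every window on that window's PLV (the raw PLV, not
the refined adjacency, which is introduced later in the pipeline) and
aligns labels to the previous window by maximal overlap. Three-phase
segmentation constants (run length 3 windows, contrast level 0.3,
slope tolerance 0.01/window, sync threshold 0.7, 5-window smoothing)
are package reconstructions of a qualitative description and are all
configurable. Detected onsets are validated against the segmentation of
the ground-truth label series, not against raw segment boundaries: the
contrast crosses threshold partway through the emergence ramp by
construction, so raw boundaries are not the right reference.

## 5. Network architecture

Implemented on an in-package NumPy reverse-mode autodiff engine
(validated against central finite differences); no deep-learning
framework is required.

* **Hypergraph convolution.** Per window: mean-pool member embeddings
  per hyperedge, score pools with a 2-layer attention MLP, softmax over
  each node's incident edges, aggregate, concatenate with the node
  embedding, linear map + ELU + layer norm + residual projection +
  dropout 0.3. Nodes in no hyperedge receive a zero aggregate.
  Parameters are shared across windows; per-window graphs are padded
  into a batch (padded rows are inert). Windows with more than 512
  hyperedges (near-global synchrony approaches C(23,3) = 1771) are
  uniformly subsampled with a seeded RNG — the attention aggregate is a
  weighted mean, which a uniform subsample approximates.
* **Selective state space.** An input-dependent *full* `d×d` state
  matrix is computationally implausible; `A(z) = −softplus(W_a z + b_a)`
  is diagonal and stable by construction. Zero-order hold:
  `Ābar = exp(ΔA)` elementwise, input factor `(Ābar−1)/A` with a series
  fallback for `|ΔA| < 1e-6`; `Δ = exp(log Δ)` is learnable per block
  (init 0.01). `B`, `C` are selective projections of the input, `D` a
  learned diagonal skip. Desk defaults: state dim 32, 2 blocks,
  2 convolution layers 16→32 (the full-scale 64→128→256 / 256 / 4 is
  selectable). The recurrence is linear in sequence length and is
  tested against a literal step-by-step re-implementation.
* **Heads.** Physics readout: phases `π·tanh`, frequencies softplus,
  coupling sigmoid, phase lag `(π/2)·sigmoid`, biases initialized at
  the chimera operating point (K ≈ 0.7, α ≈ π/6). The frequency bias
  starts at the slow (0.05 Hz) scale because the readout describes
  per-window phases whose finite differences across 2.5-s hops alias
  carrier-band rates. Task heads: chimera 2-FC + sigmoid, state 3-FC +
  softmax, time 2-FC + ReLU, each with batch norm (train mode requires
  batch ≥ 2) and dropout 0.3.

## 6. Losses and training

Weights: chimera 1.0 (focal, γ = 2, α = 0.7), state 0.8 (cross-entropy
with label smoothing ε = 0.1), time 0.5 (Huber, knot 5 minutes),
physics 0.03, structure 0.02. Inside the training loop the time loss is
computed on the horizon-normalized scale (Huber/90, identical to the
Huber of `y/90` with knot 5/90): in raw minutes its magnitude (~45 at
initialization) would dominate the clipped gradient and starve the
other tasks; the `time_loss` function itself keeps the printed
minute-scale definition.

The physics loss wraps consecutive-window phase differences to
(−π, π] (the wrap constant is gradient-transparent) and penalizes the
squared residual against the readout's own Kuramoto field. The
structure loss `−|R_sync − R_desync| + λ_div·H` clusters predicted
phases by cosine similarity (a Fiedler-sign fast path for k = 2);
`λ_div = 0.1` is a package default with no published value, and the
entropy-term sign is switchable because the printed formula penalizes
the balance entropy that its prose says is encouraged (printed form is
the default). Assignments are held fixed during backpropagation;
gradients flow through the order parameters.

Masked pretraining replaces ⌈0.15·C⌉ = 4 node feature vectors with a
learned token and reconstructs masked features (MSE, on input features
— the readout-side alternative is ambiguous) and masked binarized
adjacency rows (BCE), at AdamW lr 1e-3. Fine-tuning uses AdamW
(3e-4 main / 3e-5 physics parameters), cosine annealing, global-norm
clipping at 1.0, early stopping on validation chimera accuracy with
patience 15, and episode-level train/validation splits. Desk batch: 4
subsequences of 24 windows, two passes per epoch.

The single-minibatch learnability check runs with ε = 0: with ε = 0.1
the state term is bounded below by the smoothed-target entropy (≈ 0.43,
≈ 0.35 after weighting), so a 0.1 total-loss threshold is unreachable
by construction.

## 7. Evaluation

Stratified episode-level folds (LPT greedy plus deterministic pairwise
swap refinement; fold seizure totals within 1 of each other when sizes
allow). The alarm policy — 2 consecutive supra-threshold windows,
30-minute refractory, threshold 0.5 — is a package definition: false
positives per hour require one, and none is published. FP/hr excludes
pre-ictal and ictal time from the denominator; alarms during ictal
intervals are neither true nor false positives; horizon membership is
half-open `[onset − H, onset)`. Confidence intervals are percentile
bootstrap over episodes (1000 resamples; BCa out of scope). Cohen's
kappa uses marginal-product chance agreement and is reported undefined
when expected agreement is 1.

## 8. Benchmark problem sizes and findings

The reference experiments (module `chimerapred.benchmarks`, also run by
`scripts/acceptance.py`) use: 20 seeded 60-s recovery simulations with
0.05-rad phase noise; 10 seeded 120-s stabilization fixtures at noise
0.1; 20 full default episodes for the contrast benchmark; and a
training benchmark of 40 compact episodes (segment layout
16/12/24/6/2/8 uncompressed minutes at compression 20) with the reduced model,
30 epochs, 3 model seeds. These sizes are the package's standard
desk-scale conditions.

On the training benchmark the full model reaches ≈ 0.88 seed-mean
held-out window-level chimera accuracy (individual seeds 0.84–0.91)
against a ≈ 0.93 ceiling measured by a logistic regression on oracle
clique counts. Removing the physics losses costs ≈ 0.003 — a real but
sub-seed-noise effect at these loss weights. Replacing triplet
hyperedges with pairwise edges does *not* reduce accuracy on this
generator: the 3-cliques are a deterministic function of the pairwise
thresholded graph, so the triplet representation carries no extra
information here. The corresponding acceptance assertion is left
failing rather than weakened; distinguishing hypergraph from pairwise
representations would need a generator with genuinely higher-order
structure (e.g. triplet-coupled oscillators), which is out of scope.

## 9. Known limitations

* Synthetic-only validation: the generator reproduces phase structure,
  not clinical EEG morphology; results do not transfer claims to real
  recordings.
* The chimera here arises from frequency heterogeneity between
  communities, not from the identical-oscillator symmetry breaking of
  the strict mathematical definition.
* The mean-field parameter estimator is intentionally misspecified
  under cross-community coupling `r < 1` (documented bias).
* Per-window phase readouts alias carrier-band frequencies at the
  2.5-s hop; the physics loss therefore constrains slow inter-window
  dynamics, not the delta/alpha carriers themselves.
* BCa bootstrap, k-clique generalizations beyond k = 3, band-specific
  PLV and explainability tooling are deliberately not implemented.
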