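# Methods

This note documents the models, numerical choices and limitations of
`seizeflow`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Affine group-velocity estimation

Global image motion between two frames is modelled as an affine velocity
field `v(x) = Σ_g V_g e_g(x)` over the six generators TrX=(1,0),
TrY=(0,1), Rot=(−y,x), Dil=(x,y), ShX=(x,−y), ShY=(y,x) on the normalized
centred grid `x, y ∈ [−1, 1]` (x along the width). Normalized coordinates
make the six rates commensurate, which matters because the wavelet stage
averages them with equal weight. Under brightness constancy the rates
solve the 6×6 normal equations

    (A + λ·trace(A)/6·I) V = b,
    A_gh = Σ (e_g·∇L)(e_h·∇L),   b_g = −Σ L_t (e_g·∇L),

summed over all interior pixels and all three RGB channels with equal
weight (no grayscale conversion: colour structure is signal). Numerical
choices:

* **2×2 block averaging** of the input before estimation (the camera
  chain's down-sampling step; also halves noise).
* **Gradients** are central differences on the mean of the two frames;
  the temporal derivative is the frame difference over `dt`.
* **Interior margin.** A 10% border strip is excluded from the sums:
  border pixels carry padding/reflection artefacts that bias all channels.
* **Warp refinement** (3 passes). The one-shot linearized solve
  overestimates rates by 10–20% on fine texture because discrete central
  differences underestimate spatial gradients. The estimate is therefore
  refined by warping frame_b back by the current rates and re-estimating
  the residual; the fixed point (back-warped frame ≈ frame_a) is unbiased
  regardless of the gradient operator. Three passes bring the oracle
  regression slope to ≈ 1.05 with < 2% cross-channel leakage.
* **Regularization** λ = 1e−6 (relative, scaled by trace(A)/6) leaves
  well-conditioned solves untouched and returns the zero vector for
  blank, textureless frames.

Video is processed in independent 36-frame acquisition cycles (1.5 s at
24 fps; 35 rate samples per cycle). Cycles share no frames, so a cycle's
output never depends on its neighbours.

## Gabor spectrum and epileptic content

Each cycle's six rate signals are convolved (zero-padded, within-cycle
only) with complex Gabor kernels at K = 200 geometrically spaced
frequencies from 0.5 to 12 Hz (Nyquist at 24 fps). Kernel at frequency f:
complex exponential under a Gaussian envelope of SD `cycles/f` seconds
with `cycles = 1.5`, truncated at ±3 SD, **L1-normalized** so that
magnitude responses are comparable across frequencies. Magnitudes are
averaged over the six channels, then over time within the cycle —
excluding 5 samples at each end, where the zero-padded convolution
spreads energy across the grid and dilutes band fractions (with the trim,
a mid-band 4 Hz oscillation scores E ≈ 0.91 instead of 0.875).

The epileptic content `E` is the band fraction of that spectrum over
`[fa, fb]` (initially [2, 7] Hz). Because even white noise puts some mass
in any band, `E` is centred with the white-noise baseline `E0`, computed
by Monte Carlo (200 windows of i.i.d. Gaussian 6-channel noise, fixed
seed) through the *identical* spectral pipeline — this absorbs any
residual non-flatness of the kernel normalization, which is why `E0` is
empirical rather than analytic. `Ě = (E − E0)/(1 − E0)` then puts noise
at ≈ 0 (|mean| < 0.05 over 200 windows) and pure in-band signal near 1.

**Band-edge attenuation (limitation).** An oscillation at the band edge
(e.g. 6.7 Hz against [2, 7]) loses roughly half of its kernel response
mass outside the band: `E ≈ 0.6`, `Ě ≈ 0.28`, below the default alert
threshold. The band-fraction statistic is only fully sensitive to
frequencies interior to the band — one of the reasons the band is
learned per patient rather than fixed.

## Alert criterion

An event fires when ≥ n of the last N cycles have `Ě > T`; defaults
[N, n, T] = [7, 6, 0.4] (10.5 s look-back, 9 s above threshold). Policy
choices the rule's prose leaves open:

* **Warm-up:** before N cycles have accrued, the criterion is evaluated
  on the available buffer (an event is possible once n samples exceed T);
  a strict-N mode is available.
* **Trigger time** is the first window at which the criterion holds.
* **Refractory:** after an alert, no new event while the criterion stays
  continuously satisfied, nor within a 60 s dead time (40 windows) —
  chosen against typical tonic–clonic duration to avoid double alerts
  within one seizure.

Each event stores ±25 cycles of biomarker and flow context — enough to
serve the spectral average (−10..+15), the filling-number re-evaluation
(N ≤ 15 ending at the trigger) and the clustering signature (±20).

## Adaptation layers

**Band selection.** For each validated seizure, the per-cycle spectra of
the 26 windows from 10 before to 15 after the trigger (trigger counted in
the "after" span) are frequency-mean-subtracted and averaged; with M(f)
the across-event mean and SD(f) the across-event standard deviation,

    K(f) = M(f) / (|M(f)| + SD(f))

is bounded in [−1, 1], equals sign(M) where events agree perfectly and is
damped wherever they disagree. The new band is the contiguous run around
the global peak where `K > 0.1·max K`; a contiguous interval (rather than
the literal super-threshold set, which may be disconnected) is enforced
because the energy fraction E integrates over an interval.

**Parameter optimization.** On a grid (T = 0.05..0.95 step 0.01,
N = 2..15), the filling number n(T, N) is the minimum over training
seizures of the count of super-threshold cycles among the N ending at the
trigger; biomarkers are recomputed from stored flow context under the
current band, never reused from detection time. Maximizing
`C(T, N) = T·(2n − N)` and adopting n = n(T, N) guarantees every training
seizure still satisfies the criterion at its trigger; the code re-verifies
this by running the detector over every training context and raises if it
ever fails. Ties break toward larger T, then smaller N (prefer selectivity
over latency); cells with n = 0 are excluded since they cannot guarantee
preservation. Adaptation requires ≥ 10 validated seizures and uses at
most the 50 most recent (older events may reflect stale conditions).

## Unsupervised validation

Event signature: `P(q) = ⟨std_t V_g(t)⟩_g` over the 41 cycles centred on
the trigger. Pairwise distance:

    D_ij = min_{|τ| ≤ 10} Σ_q |P_i(q+τ) − P_j(q)| / Σ_q |P_i(q+τ) + P_j(q)|

with sums over the overlap of the shifted pair, which keeps D symmetric
and in [0, 1]; the ±10-window lag search absorbs trigger-time jitter
between events. A pair of all-zero signatures is defined as distance 0
(identical signals; avoids 0/0). An event is accepted as a seizure when
its mean distance to all other recorded events is ≤ ε; ε = 0.5 equals the
expected distance between unrelated random signatures (for i.i.d.
exponential energies, E|X−Y|/E(X+Y) = 1/2, confirmed by Monte Carlo),
with ε = 0.45 as a conservative preset. The classifier touches only
flow-derived signatures: neither detection parameters, nor the band, nor
raw video enter it.

## Synthetic study conditions

No patient video can be distributed, so the generator emulates the motion
structure the detector assumes, with exact ground truth:

* **Texture:** smoothed Gaussian noise per RGB channel (σ = 2 px),
  default 240×320. Rendering integrates the per-frame affine rates into a
  cumulative transform and samples the pattern bilinearly with reflection
  padding (no black borders), plus i.i.d. Gaussian pixel noise
  (SD = 0.01 of full range).
* **Seizures:** 20–60 s sinusoidal oscillation of the translation
  channels, frequency drawn from the clonic band, rate amplitude 0.6 1/s.
* **Normal movements:** 10–20 s of sub-1-Hz wander, generated as a
  band-limited *position* trajectory (rate RMS 0.3 1/s, excursion capped
  at 0.15 normalized units so the scene stays in frame) and
  differentiated to rates.
* **Tremor:** 2–5 s bursts at clonic-like frequencies — hard negatives
  that share the seizure's spectral content but not its duration.
* **Event contexts:** pre-built detected-event records for clustering and
  optimization studies. Seizure events are one long (~40 s) stereotyped
  convulsion; false events are heterogeneous successions of 2–4 short
  bursts, mirroring the dominant false-positive source in this
  population (brief motor paroxysms that are not tonic–clonic seizures).
  The quiet-window flow-noise floor (0.003 1/s) is calibrated to what the
  flow estimator returns for a static textured scene with 1% sensor noise.
* Per-frame displacement is capped at 10% of the image width — the
  single-step flow linearization regime.

What the fixtures do **not** model: articulated bodies, bedding
occlusion, lighting changes, infrared night mode, camera auto-exposure,
and the real variability of human seizure semiology. Passing tests
demonstrate the algorithm chain is implemented correctly and behaves as
designed under its own assumptions; they are not clinical evidence.

## Problem sizes

The whole-system checks run at sizes chosen to exercise the full chain:
flow-oracle warps on 96×128–120×160 patterns; the end-to-end rendered
trial at 120×160 over 560–700 s (two seizures drawn from 2.5–6 Hz —
interior to the band, see the band-edge note — among five normal and five
tremor segments); band-recovery and preservation runs on 1100 s
group-velocity streams with ten seizures each, ten seeded repetitions per
frequency; clustering separation on 8 + 4 events over ten seeded runs.

## Known limitations

* Band-edge seizure frequencies are attenuated by the band-fraction
  statistic (above).
* The ±10-window lag search bounds how much trigger jitter the distance
  can absorb; events misaligned by more do not cluster.
* Convergence of the adaptation loop is only observed empirically (the
  stability tests show optima move by at most one grid step on
  stationary synthetic data); no convergence proof is attempted.
* Missed seizures (false negatives of the online detector) never enter
  the validation or training sets; the system cannot learn from events it
  never saw.
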