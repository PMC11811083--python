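# Methods

This note records the models implemented in `imdnm`, the assumptions they
make, the numerical choices behind the fits, and what the synthetic-data
experiments do and do not establish.

## 1. Windowed linear dynamic network model of iEEG

Each preprocessed recording (channel × sample, microvolts) is cut into
non-overlapping windows (default 500 ms) and each window is modeled as a
discrete-time linear system `x(t+1) = A_j x(t) + e(t)`. The per-window
transition matrix is the least-squares solution of the one-step regression;
the window must contain at least `n_channels + 1` samples so the regression
is identifiable, and the windowing refuses shorter settings by naming the
minimum duration. The sequence is summarized as `Ā = (1/T) Σ_j |A_j|`:
intracranial EEG cannot reliably distinguish excitatory from inhibitory
coupling at this spatial scale, so only interaction *strength* is retained.
Per-window matrices are kept on the result object so temporal stability can
be studied downstream; no per-window normalization is applied before
averaging (whether to normalize each `A_j` first is genuinely open — we do
not, and document it here).

Degenerate windows: when the regressor Gram matrix is rank-deficient
(relative singular-value ratio below 1e-10), a deterministic ridge with
`λ = 1e-6 · trace(X₁X₁ᵀ)/N` is used and logged. This is routine rather
than exceptional under a common-average reference, which places the data on
an (N−1)-dimensional subspace by construction; an all-zero window returns a
zero matrix with a warning.

Preprocessing uses zero-phase (forward–backward) 4th-order Butterworth
designs for the 0.5–300 Hz band-pass and the 60±2 Hz notch: the one-step
regression is sensitive to phase lag, which zero-phase filtering avoids.
When the band's upper edge reaches Nyquist (common at clinical sampling
rates of 500–600 Hz) it is clipped to 0.99×Nyquist with a logged warning.
Channels flagged bad are dropped *before* the common average so artifacts
cannot leak into the reference.

### Source–sink indices

Row strengths (inbound, diagonal excluded) and column strengths (outbound)
of `Ā` are converted to tie-averaged ascending ranks scaled by `1/N`, so
both coordinates live in `(0, 1]` and are invariant to amplitude scale.
The ideal sink sits at `(rr, cr) = (1, 1/N)` and the ideal source at
`(1/N, 1)`; √2 is the largest attainable distance in the unit square, so
the sink index `SI = √2 − distance-to-ideal-sink` lies in `[0, √2]`. Top
sources and top sinks are the `ceil(q·N)` channels with the largest source
and sink indices (default `q = 0.10`; no canonical fraction exists, so it
is configurable), with stable ordering as the tie-break. Source influence
`SF_i` is the mean of `Ā[i, s]` over top sources `s ≠ i` and sink
connectivity `SC_i` the mean of `Ā[i, k]` over top sinks `k ≠ i` — both
read *inbound* influence, per the row convention; reading SC as outbound
instead is a defensible alternative that the configuration does not
currently expose. The SSI is the product `SI·SF·SC`, min–max rescaled
within the patient, so exactly one channel reaches 1 barring ties; an
all-zero network yields all-zero SSI with a warning rather than 0/0. Note
one small-N artifact: when `ceil(q·N) = 1`, the single top sink has no
"other top sinks" and its SC is 0 by convention — meaningful sink
connectivity needs at least two top sinks, as in any realistic montage.

## 2. Cross-spectral effective connectivity of rs-fMRI

The generative model for ROI series is a continuous-time linear stochastic
system `ż = Az + v`, observed through the canonical double-gamma
hemodynamic kernel (gamma densities peaking at 6 s and 16 s, undershoot
ratio 1/6; its Fourier transform is evaluated analytically and normalized
to unit DC gain) with additive observation noise. Off-diagonal `A` entries
are signed rates in 1/s; the diagonal is fixed at −0.5 s⁻¹ as a stability
anchor and is excluded from estimation, reduction, averaging and
reporting — self-coupling is not of interest here, and a signed
excitatory/inhibitory readout cannot live on a log scale, so only the
amplitudes and slopes (α_v, β_v per ROI; α_e, β_e shared) are
log-parameterized. Endogenous fluctuations and noise have power-law
spectra `α ω^(−β)` with ω = 2πf.

### Fitting

1. **Empirical CSD.** A least-squares VAR (default order 8) on the demeaned
   series gives `S(f) = TR · Φ(f)⁻¹ Σ_u Φ(f)⁻ᴴ`, evaluated on a log-spaced
   grid in [1/128, 0.25] Hz. The default grid has 16 points: with the
   spectral smoothing the autoregression imposes, a denser grid's
   neighboring points are strongly correlated and an independent-feature
   likelihood becomes overconfident (posterior z-scores of a known-zero
   coupling had standard deviation ≈ 2 at 32 points versus ≈ 1.1–1.3 at
   12–16 in our calibration runs). The upper bound deliberately extends
   above the conventional 0.1 Hz resting-state cutoff.
2. **Features and scaling.** Each frequency's matrix is whitened by its
   mean auto-spectrum; the data spectrum is rescaled once so the
   zero-parameter model (α = 1) matches overall observed power, keeping
   the tight log-amplitude priors sensibly centered for arbitrary BOLD
   units. Features are the diagonal (real) plus real and imaginary upper
   triangles.
3. **Noise level.** The feature noise variance is a fixed scalar estimated
   from a split-half re-estimate of the empirical CSD (half the mean
   squared half-to-half difference, divided by two). Estimating it from
   fit residuals instead collapses the noise floor once the model fits
   well and makes both the posterior and the evidence overconfident —
   model reduction then refuses to switch off genuinely absent
   connections. The split-half level ties the likelihood to the actual
   sampling noise of the spectral estimator.
4. **Optimization.** Gauss–Newton/Levenberg–Marquardt ascent on the
   Laplace free energy with numerical Jacobians (step 1e-5), Gaussian
   priors `A_off ~ N(0, 1/64)`, `log α, log β ~ N(0, 1/16)`, damping
   increased eightfold on rejection and steps accepted only if the free
   energy does not decrease — the reported trajectory is monotone by
   construction. Candidates with unstable `A` (any eigenvalue real part
   ≥ −1e-6) are rejected outright, and the forward model refuses unstable
   matrices. Convergence: free-energy change < 1e-3 nats, or a stationary
   point at which no damped step improves; only exhausting 64 iterations
   flags `non_converged`, returning the best iterate.

### Model reduction and averaging

For a reduced prior that pins a subset of couplings to 0 (prior variance
1e-8), the change in log evidence and the reduced posterior mean follow in
closed form from the Gaussian prior/posterior pair — exact for a linear
model, and within 1 nat of explicit refits on 2-ROI enumerations in our
checks. All `2^m` on/off patterns are enumerated when the number of
couplings `m ≤ 8`; beyond that a greedy search repeatedly switches off the
coupling whose removal most improves evidence until none improves it,
scoring every visited pattern. Averaging keeps the best 256 patterns,
weights them with a max-shifted exponential of their evidence (avoiding
underflow), and averages the reduced posterior means. The per-ROI score is
the positive part of the outbound (column) couplings, summed and min–max
normalized within the subject; a flat profile warns and scores zero.

Two caveats worth knowing. First, evidence differences inherit the
approximations above; with couplings far outside the prior scale (e.g.
±0.3 against a prior SD of 0.125), shrinkage of strong couplings is
partially compensated by small spurious estimates elsewhere — a standard
Bayesian-shrinkage effect that degrades *structure* recovery even while
*sign* and *score* recovery remain excellent. Second, the ROI guard
(≤ 8 ROIs, ≥ 8 volumes per ROI) reflects the desk-scale design; the
model-space cap of 256 matters only beyond 3 ROIs.

### ROI construction helpers

The first-eigenvariate summary takes the voxels passing a per-voxel
significance threshold, demeans them, and returns the first right singular
vector, sign-aligned with the mean passing-voxel series and scaled to unit
variance. Masks whose overlap — intersection over the *smaller* mask —
exceeds 0.8 are unioned transitively.

## 3. Combination and outcome evaluation

The combined index is the plain average of the two per-region scores and
requires both modalities (no imputation; missing rows are flagged).
Patient-level scores are unweighted means over the patient's surgically
evaluated regions by default — region scores are normalized within the
patient over *all* modeled regions, so a patient whose surgical plan missed
the true onset region keeps low planned-region scores even though some
region in the full map always scores 1. Averaging over all regions instead
is available via `restrict_to_plan=False`.

The threshold scan covers [0, 1] inclusive at a step that must divide the
interval evenly (default 0.05, i.e. 21 points), predicting a good outcome
when the score is at or above threshold; this direction — high score on the
evaluated plan predicts success — is stated explicitly in the result object
rather than inferred. The optimal threshold maximizes balanced accuracy
(robust to the typical imbalance of surgical cohorts), ties resolved toward
the smallest threshold. Resection overlap counts a region when its score
exceeds 0.9 and at least 80% of its voxels lie inside the resection mask
(the denominator is the region, not the resection), reported as a
percentage of high-scoring regions per modality and outcome group. The
between-modality association is a Spearman rank correlation (scipy's
implementation, asymptotic p at these sample sizes).

## 4. What the synthetic data emulate — and what they do not

`simulate_ieeg` plants sink channels in a stable transition matrix: inbound
gain 0.4, outbound 0.05 against a background of 0.1 (all jittered by
U(0.75, 1.25) so ranks are not degenerate, signs random, diagonal ≈ 0.5),
rescaled to spectral radius 0.95 — rescaling preserves all rank structure.
The system is driven by unit white noise, scaled to ~50 µV, and observed
with white measurement noise at a stated variance ratio (`snr`); with
`snr = inf` both noises are off and the trajectory relaxes from a random
state, making the generator exactly recoverable. An optional
regime-switching mode re-draws background couplings piecewise. Measurement
noise attenuates least-squares estimates non-uniformly (high-variance
channels resist attenuation), which is part of why sink recovery degrades
gracefully rather than abruptly as snr falls.

`simulate_bold` synthesizes ROI series directly in the frequency domain:
at each FFT frequency the model cross-spectrum is factorized (Cholesky with
1e-12 jitter) and complex Gaussian coefficients are drawn, so the realized
spectrum matches the generative model by construction. The planted driver
ROI has outbound couplings +0.4 s⁻¹ against ±0.1 backgrounds; α_v = 1,
β_v = 1, α_e = 0.5, β_e = 1. Power-law spectra are held constant below
1/128 Hz: real acquisitions are high-pass filtered around 100 s, and
unbounded ultra-slow power is both unphysical for analyzable data and a
source of systematic finite-order autoregression bias inside the analysis
band.

`simulate_cohort` builds 17-patient cohorts mirroring a realistic surgical
mix (2–4 candidate regions per patient in 1:7:8 proportions, ages 3–15,
~53% female, Engel sub-splits 2:1 within good and 1:4 within poor
outcomes). Each patient gets an iEEG recording (12 s at 250 Hz, snr 0.65,
3 channels per region plus 2 unmapped contacts; the planted sinks are the
onset region's channels) and a BOLD series (220 volumes at TR 2 s, onset
region planted as driver), disjoint 3×3×3 voxel blocks as region masks on
a 15×15×6 grid, and a resection equal to the union of the planned regions:
good-outcome patients' plans contain the onset region, poor-outcome plans
exclude it. This operating point was chosen so each single modality errs
occasionally (mean balanced accuracy ≈ 0.95–0.96 over 20 seeded cohorts)
while the combined index stays above both (≈ 0.97–0.98) — the regime in
which combining modalities is meaningful rather than saturated.

What passing these experiments does **not** show about clinical data: the
generators share the estimators' model families (linear dynamics, power-law
spectra, the same hemodynamic kernel), contain no epileptiform transients,
spikes, high-frequency oscillations, artifacts, electrode-geometry effects
or inter-subject variability, assign outcomes deterministically from
resection coverage, and use far fewer channels and regions than clinical
montages. Recovery rates here are upper bounds under model-consistent
conditions, not clinical performance estimates.

## 5. Known limitations

- The hemodynamic transfer function is a fixed canonical kernel; regional
  hemodynamic variability is not modeled and would be partially absorbed
  by α_v and misattributed phase.
- The spectral likelihood treats features as independent Gaussians with a
  scalar noise level; residual correlation between features makes evidence
  differences approximate (the split-half calibration mitigates but does
  not remove this).
- Greedy model reduction explores a path-dependent subset of patterns
  beyond 8 couplings; evidence-weighted averages over that subset can
  differ from the exhaustive answer.
- EDF files are read (via mne) but not written; the portable on-disk
  format is the delimited matrix + JSON sidecar pair.
- One top sink implies zero sink connectivity for that channel (see §1);
  use `q` large enough that `ceil(q·N) ≥ 2` on small montages.
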