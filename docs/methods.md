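# Methods

This note records the models implemented in `petquench`, their
assumptions, the numerical choices made where a choice was genuinely open,
and what the synthetic data do and do not establish about real
measurements.

## Two-state quenching kinetics

PET quenching is treated as an all-or-nothing two-state (telegraph)
process: a molecule is dark while the fluorophore and quencher ring
systems are in contact and fully fluorescent otherwise. For a stationary
telegraph process with contact-formation rate k_form (bright → dark) and
dissociation rate k_diss (dark → bright), the bright-state indicator has
the normalized autocorrelation

    G(τ) = 1 + (F_dark / F_bright) · exp(−(k_form + k_diss) τ),

with stationary fractions F_bright = k_diss/(k_form+k_diss),
F_dark = 1 − F_bright. The dynamic term is therefore a single exponential
G_dyn(τ) = a_r exp(−τ/τ_r) with

    τ_r = 1/(k_form + k_diss),     a_r = F_dark/F_bright = k_form/k_diss.

### The two rate conventions

The conversion widely used alongside PET-FCS fits reads
τ_r = 1/(k_on + k_off) and **a_r = k_off/k_on**, with k_on interpreted as
the contact-formation rate. The telegraph closed form above gives the
amplitude as the *inverse* ratio: contact formation populates the dark
state, so a_r = k_formation/k_dissociation. The two readings coincide only
for symmetric rates. `rates_from_dynamics` therefore carries an explicit
`convention` flag:

* `"as_printed"` (default) — a_r = k_off/k_on, matching the conversion as
  commonly printed and reproducing rate tables derived with it exactly;
* `"telegraph_oracle"` — a_r = k_on/k_off, the algebra consistent with the
  two-state process itself; simulation-recovery tests use this convention
  because the simulator's ground truth obeys it.

Both conventions share τ_r, are exact inverses of `dynamics_from_rates`,
and differ only in which physical rate is labeled k_on. The discrepancy is
surfaced rather than silently resolved; any report states the convention
next to the rates, and the stored (a_r, τ_r, convention) always reproduce
the stored rates.

## The composite FCS model

Measured confocal correlation curves are fit with

    G(τ) = γ/N · (1 + τ/τ_D)⁻¹ (1 + τ/(p² τ_D))^−1/2
           · (1 − A_ab e^{−τ/τ_ab})
           · (1 + T/(1−T) e^{−τ/τ_T})
           · (1 + a_r,1 e^{−τ/τ_r,1} + a_r,2 e^{−τ/τ_r,2}),

the product of free 3D diffusion through a Gaussian focus (lateral 1/e²
radius w, axial/lateral ratio p, τ_D = w²/4D), photon antibunching,
triplet blinking, and up to two conformational-dynamics terms.
γ = 2^−3/2 is the shape factor of the 3D-Gaussian detection profile and is
held fixed (overridable); N is the mean occupancy of the profile-integral
volume V_obs = (π/2)^{3/2} w² (p w), so the amplitude extrapolates to γ/N.
The expression is the excess (fluctuation) part: a raw curve that tends to
1 at long lags equals 1 + G(τ). The triplet factor is implemented as the
decaying exponential e^{−τ/τ_T}; a growing exponential is unphysical and
the measured curves decay through the triplet regime.

Model curves are strictly decreasing in τ whenever A_ab = 0; T = 1 is
rejected as singular. Lags are seconds internally; nanoseconds and
reciprocal microseconds appear only at I/O boundaries.

## Correlators

`direct_correlation` evaluates the definition
G(τ) = ⟨I(t)I(t+τ)⟩/(⟨I⟩⟨I⟩) by brute force with *symmetric
normalization*: at each lag the two means are computed over the two
overlapping windows. This removes the leading finite-length bias and makes
the estimator exactly reproducible by hand, which is why it serves as the
oracle for everything else.

`multiple_tau_correlation` uses the standard quasi-logarithmic scheme:
m = 16 linear lags at the base bin width, then m/2 lags per level with the
bin width doubling each level, both channels re-binned at the current
width. Photon timestamps are correlated *sparsely* (pair counting via
binary search on binned indices) — arithmetic identical to correlating the
binned counts, at photon-limited cost. The deterministic distortion from
re-binning an exponential of time constant τ at bin width b is
O((b/τ)²/12) at the shallowest retained lag (lag ≥ (m/2+1)·b), well below
the 2% oracle-equivalence tolerance verified in the tests. The lag grid
starts at one base bin (τ = 0 and its shot-noise term are excluded), and
the deepest lags default to an eighth of the record (a quarter of a
segment when segment errors are requested). The base bin width and m are
configurable; defaults follow common multiple-tau practice.

Uncertainties follow the ten-segment protocol: the record is split into
equal-duration parts, each is correlated with identical settings, and the
per-lag value/σ are the across-segment mean and standard error.

Binary MD quenching signals are correlated with the direct estimator on a
logarithmic lag subset (a 10⁶-frame series is small enough that exactness
is preferred over speed), restricted to lags with at least 100
contributing window pairs.

## Fitting

Weighted least squares (lmfit, Levenberg–Marquardt) minimizes
Σ((G_data−G_model)/σ)². Covariance-based 95% intervals use the unscaled
covariance (σ taken at face value), so doubling every σ doubles every
interval and leaves the estimates unchanged. Bounds keep the optimizer
physical: times in [1 ps, 10 s], amplitudes in [0, 10], T in [0, 0.99].
Non-convergence and active bounds are flagged on the result, never raised.

Two structural measures make the composite fit well-posed:

* **Timescale ordering.** The three bunching factors are mutually
  exchangeable for an optimizer. They are identified the way the curve
  regimes are read physically — dynamics faster than triplet, triplet
  faster than diffusion — by fitting each free time below τ_D as a ratio
  in (0, 1] of the next slower one. Without the constraint a near-constant
  pseudo-triplet with T → 1 (amplitude T/(1−T) unbounded) is exchangeable
  with a rescaling of N.
* **Staged multistart.** The half-decay heuristic lands on the dynamics
  timescale when the curve amplitude is dominated by fast quenching, so a
  diffusion-only fit of the upper half of the lag range first pins down
  (N, τ_D, offset); full fits then start from a small deterministic grid
  of triplet/dynamics seeds and the lowest chi-square wins. Fits are
  deterministic for identical inputs.

A small additive baseline (`offset`) is fit alongside the model; finite
records retain a residual constant (finite particle number and
finite-segment normalization) that otherwise biases τ_D.

**Parameter confidence intervals in the pipeline.** Per-lag SEM weighting
treats lags as independent, but multiple-tau lags share photons and slow
occupancy fluctuations correlate whole lag regions, so covariance-based
intervals understate parameter uncertainty. `run_fcs_pipeline` therefore
reports leave-one-segment-out jackknife intervals: the mean curve is refit
with each of the ten segments deleted in turn, and the jackknife standard
error with a t(n−1) quantile gives the 95% interval (each refit keeps 90%
of the photons, so the refits stay well-conditioned). The covariance
intervals are retained under `ci95_covar`.

**Model comparison.** One- and two-component dynamic fits are compared by
an F-test on the nested chi-squares at α = 0.05 (configurable), with the
lag-1 autocorrelation of the single-component weighted residuals reported
as a structure diagnostic. The recommendation is advisory; calibration
(false preference ≤ 10% on single-exponential data, power ≥ 90% on
components separated 5× in time) is verified in the tests.

## Trajectory analysis

* **RMSD** is computed after optimal rigid-body superposition of the
  analyzed selection (Kabsch, via the batched SVD trace identity;
  numerical floor ~10⁻⁷ nm from cancellation). Superposition before RMSD
  is applied throughout — the heavy-atom selection analyzed is also the
  fit selection. The implementation is cross-checked against an
  independent Kabsch implementation in the tests.
* **Single-linkage clustering** builds the connected components of the
  graph with an edge wherever pairwise RMSD < cutoff (default 0.25 nm).
  Because superposed RMSD is a pseudometric, distances to a small set of
  pivot frames give triangle-inequality lower bounds that prune most pair
  evaluations; the construction remains exact and is verified against
  brute-force connected components. Intended scale is ≤ ~2×10⁴ frames.
  Clusters are numbered by population; the representative is the medoid
  (member minimizing summed RMSD), since averaging coordinates of
  disordered frames produces unphysical structures.
* **End-to-end regimes.** The Cβ(residue 1)–Cβ(residue 14) distance is
  assigned close (d < 1.3 nm), open (d > 2.5 nm) or intermediate (strict
  inequalities; a distance exactly at a threshold is intermediate).
  Transition counting uses last-assigned-regime (hysteresis) semantics:
  intermediate frames keep the previous regime, an excursion into the band
  and back does not count, and both crossing directions contribute to N_T;
  the rate is N_T divided by the total simulation time. Counting both
  directions matches the reading of N_T as a mean rate of opening *and*
  closing events (e.g. 1503 switches in 30 µs → 50.1 µs⁻¹, the arithmetic
  the tests verify); a one-direction reading is also conceivable and is
  documented here, but the both-directions rule is what is implemented.
* **Quenching classification.** A frame is dark iff the distance between
  the unweighted geometric centers of the fluorophore and quencher ring
  systems is below r* = 0.55 nm (strict; exactly r* is fluorescent). The
  tryptophan ring group defaults to its nine side-chain ring atoms; the
  dye's ring system has no standard atom naming and must be supplied in
  the criterion. The quenching autocorrelation supports an analysis-window
  start offset to discard an initial equilibration period, mirroring the
  protocol of fitting the full window and the equilibrated window
  separately.

## Synthetic data: what it emulates, and what it does not

Generators exist for every input class, each with exact, known ground
truth:

* **Telegraph signals** are simulated event-driven in continuous time
  (exponential dwells, stationary initial state — avoiding equilibration
  bias) and sampled on the requested grid, so dwell-time distributions and
  the single-exponential correlation are exact by construction.
* **Two-well distance series** superpose Gaussian observation noise on a
  hidden telegraph between a close and an open well; the hidden transition
  count is returned for oracle comparisons. Well positions inside the
  intermediate band warn rather than fail.
* **Planted ensembles** draw frames from weighted center structures with
  isotropic coordinate noise, then apply a random rigid rotation and
  translation per frame so clustering must superpose. Separability:
  within-cluster pair RMSD concentrates near √2·sd, so planted clusters
  are recovered at cutoff c when √2·sd is safely below c and all center
  pairs are farther than c + 6·sd apart (no chaining).
* **Photon streams** come from a hybrid scheme. Brownian particles move in
  a periodic box (all sides 10 w; the particle count is N·V_box/V_obs);
  the diffusion envelope — the summed 3D-Gaussian detection weights — is
  piecewise constant on a coarse grid (default τ_D/50, guard at τ_D/10),
  and candidate photons are drawn from it as an inhomogeneous Poisson
  process and attributed to particles by intensity share. Triplet and
  quenching states are then evaluated *exactly* at the candidate times by
  analytic two-state Markov propagation, so the fast blinking factors
  carry no time-step error at all — this is what makes nanosecond
  quenching dynamics affordable inside a microsecond diffusion problem. An
  optional exponential excited-state dwell after each accepted emission
  produces the antibunching dip; timestamps are quantized to the tick
  (16 ps default), identical quantized stamps on one channel are merged
  (a detector cannot register two photons in one tick), and an optional
  50:50 random split emulates the beam-splitter arrangement. Brownian
  steps are generated in float32 (rounding ~10⁻⁷ of the box, far below
  the step itself).

Not modeled: detector afterpulsing and dead time, background and scatter,
excitation saturation and the laser-power dependence of the triplet
amplitude (T and τ_T are direct inputs), vendor TTTR file formats, and
photophysics beyond two-state triplet/quench blinking. Passing tests
therefore establish that the analysis chain recovers known ground truth
under ideal detection — not that real detector artifacts are handled.

## Standard study conditions and problem sizes

The validation suite runs at desk scale with conditions fixed in
`standard_photon_spec` and the test fixtures:

* Quenching kinetics k_form = 8.4 µs⁻¹, k_diss = 5.5 µs⁻¹
  (τ_r = 71.9 ns, a_r ≈ 1.53 in the telegraph convention) — the
  equilibrated-trajectory rate regime.
* Trajectory-side records: 30 µs at 30 ps sampling (10⁶ frames), matching
  the data volume of a long explicit-solvent trajectory; 20 seeds for
  recovery statistics.
* Photon-side records: w = 195 nm, p = 2, τ_D = 50 µs (D ≈ 190 µm²/s, the
  physical regime of a small labeled peptide), triplet T = 0.2 with
  τ_T = 2 µs, occupancy N = 0.3 (sub-nanomolar, single-molecule regime),
  and a bright emitter (2×10⁶ counts/s at focus center) over 0.3 s per
  replicate (~7×10⁴ photons, ~6000 diffusion transits). The brightness
  and occupancy compress the information of an hours-long measurement
  into a tractable record while keeping every fitted parameter
  well-conditioned; 50 replicates for confidence-interval coverage.
* Clustering: 600-frame, 20-atom planted ensembles with weights
  60/30/10%, within-cluster sd 0.03 nm, centers ≥ 1 nm apart, cutoff
  0.25 nm; brute-force oracle instances ≤ 2×10³ frames.

## Known limitations

* The exact single-linkage construction is not intended beyond ~2×10⁴
  frames; larger ensembles should be strided first.
* The photon simulator's diffusion envelope is piecewise constant; lags
  below the envelope step carry a small deterministic smoothing of the
  *diffusion* factor only (the blinking factors are exact). With the
  default step of τ_D/50 the effect is below the statistical resolution
  of the validation records.
* Jackknife parameter intervals assume the ten segments are exchangeable;
  strong non-stationarity across a record (e.g. drift) violates this and
  shows up as inflated intervals rather than as a diagnosis.
* The F-test for the second dynamic component assumes approximately
  Gaussian residuals on the fitted lag grid; its calibration is verified
  on synthetic curves with independent per-lag noise, which correlated
  real residuals only approximate.
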