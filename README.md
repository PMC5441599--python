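# petquench

Tools for comparing the end-to-end contact dynamics of fluorescently
labeled peptides between PET-FCS measurements and molecular-dynamics
trajectories.

In PET-FCS (photoinduced-electron-transfer fluorescence correlation
spectroscopy) a dye at one end of a flexible peptide is quenched, in an
effectively all-or-nothing fashion, whenever a tryptophan at the other end
comes into van-der-Waals contact. The fluctuating photon stream from a
confocal microscope then carries the contact kinetics, and an MD trajectory
of the same labeled peptide can be reduced to a binary dark/fluorescent
signal with a simple ring-center distance criterion (r* = 0.55 nm). Both
routes end in the same observable — the quenching correlation
G_dyn(τ) = a_r·exp(−τ/τ_r) — so they can be compared quantitatively. This
package implements both analysis chains and the synthetic data needed to
validate them end to end:

* **`correlate`** — the normalized intensity correlation
  G_ij(τ) = ⟨I_i(t)I_j(t+τ)⟩ / (⟨I_i⟩⟨I_j⟩), computed brute-force (the
  oracle) or with a multiple-tau correlator (m = 16 points per level, bin
  width doubling per level) that handles photon timestamps sparsely;
  per-lag uncertainties from ten equal-length segments.
* **`models`** — the composite FCS model
  G(τ) = γ/N · (1+τ/τ_D)⁻¹ (1+τ/(p²τ_D))^−1/2 · (1−A_ab e^{−τ/τ_ab}) ·
  (1+T/(1−T) e^{−τ/τ_T}) · (1+Σ a_r,i e^{−τ/τ_r,i}) with γ = 2^−3/2,
  the conversion τ_r = 1/(k_on+k_off), a_r = k_off/k_on between dynamic-term
  parameters and microscopic contact rates (both printed and
  telegraph-consistent conventions), dynamic-part isolation, and
  D = w²/(4τ_D).
* **`fitting`** — weighted nonlinear least squares (lmfit) with 95%
  confidence intervals, timescale-ordered parameterization, and an F-test
  comparison of one- vs two-component dynamic models.
* **`traj_analysis`** — heavy-atom Kabsch RMSD, single-linkage
  conformational clustering (0.25 nm cutoff, populations, medoids),
  open/close end-to-end regimes (1.3 / 2.5 nm thresholds on the Cβ–Cβ
  distance) with hysteresis transition counting, and the dark/fluorescent
  classification with its autocorrelation and two-state fit.
* **`synthetic_data`** — exact continuous-time telegraph signals, two-well
  distance series, planted-cluster ensembles, and a confocal photon-stream
  simulator (Brownian particles, 3D-Gaussian detection profile, triplet and
  quenching blinking, optional antibunching, 50:50 beam-splitter channel
  split, 16 ps timestamps) whose expected correlation is the composite
  model factor by factor.
* **`pipeline`** / **`petquench` CLI** — the two end-to-end analyses and a
  JSON comparison report.

## Worked example

Reduce a 30 µs binary quenching signal (10⁶ frames at 30 ps, the data
volume of a long explicit-solvent trajectory) to contact rates:

```python
from petquench import (TelegraphParams, simulate_telegraph,
                       quench_autocorrelation, rates_from_dynamics,
                       diffusion_coefficient)

signal = simulate_telegraph(TelegraphParams(k_form_per_us=8.4,
                                            k_diss_per_us=5.5,
                                            dt_ns=30.0, n_steps=1_000_000,
                                            seed=1))
curve, fit = quench_autocorrelation(signal, convention="telegraph_oracle")
print(f"a_r    = {fit.a_r:.3f}")
print(f"tau_r  = {fit.tau_r_ns:.1f} ns")
print(f"k_form = {fit.k_on_per_us:.2f} /us,  k_diss = {fit.k_off_per_us:.2f} /us")
```

prints

```
a_r    = 1.540
tau_r  = 71.2 ns
k_form = 8.51 /us,  k_diss = 5.53 /us
```

— the fitted amplitude estimates the dark/bright occupancy ratio
(truth 8.4/5.5 ≈ 1.527), the relaxation time estimates 1/(k_form+k_diss)
(truth 71.9 ns), and both generative rates are recovered to a few percent
from 30 µs of signal.

The printed-convention rate conversion and the focal-geometry relation:

```python
k_on, k_off = rates_from_dynamics(0.67, 80.4e-9, convention="as_printed")
# -> k_on = 7.4 /us, k_off = 5.0 /us
diffusion_coefficient(195.0, 51.0)
# -> 186.4 um^2/s  (w = 195 nm, tau_D = 51 us)
```

A full photon-side analysis (simulate → cross-correlate with segment
errors → composite fit with model comparison → isolate the dynamic part →
rates) is one call:

```python
from petquench import run_fcs_pipeline, standard_photon_spec
report = run_fcs_pipeline(standard_photon_spec(seed=7), {"base_bin_s": 1e-8})
```

The CLI mirrors the library: `petquench simulate|correlate|fit|mdanalyze|report`.

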