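# Methods

## Scope and model

`interfep` analyses 1D free-energy profiles G(z) of small solutes crossing a
vacuum–water–vacuum slab, with z the distance from the slab centre. The
analysis chain is: biased (umbrella-sampled) reaction-coordinate time
series → per-window histograms → WHAM → vacuum referencing → symmetrization
→ bootstrap errors → landmark free energies → Boltzmann concentration
enhancements and Henry's-law comparison. Real umbrella-sampling output (one
plain-text time series per window plus a metadata file of centres and force
constants) is accepted directly; for validation and desk-scale operation the
package generates its own data with known ground truth.

### The synthetic surface

`PotentialModel` is an even function of z built from three levels: a vacuum
plateau `g_vacuum` (0 by convention), a bulk plateau `g_bulk`, and an
interfacial well reaching `g_surface_min` at ±`z_interface`. The
plateau-to-plateau transition is a compact-support quintic smoothstep of
half-width `w_switch` centred on the slab edge, so G is exactly `g_bulk` at
the centre and exactly `g_vacuum` in vacuum (C² smooth everywhere); the
wells are mirrored Gaussians of half-width `w_interface` whose amplitude is
calibrated numerically (Brent root find on the grid minimum) so that
min G = `g_surface_min` exactly. Ground truth for the landmarks is
therefore ΔG_gs = `g_surface_min` and ΔG_hydr = `g_bulk` by construction.

Default geometry (the slab itself is not part of the data, so these are the
package's own choices): box half-extent `z_max` = 4 nm, interface at 1.6 nm
(slab roughly half the 8 nm box), `w_interface` = 0.25 nm, `w_switch` =
0.2 nm — leaving vacuum, interface and bulk regions each ≥ 1 nm wide inside
the ±3.5 nm restraint range.

### Window placement

`make_window_scheme(n_positions, position_spacing, n_replicates, z_min,
z_max)` reproduces the multi-solute design: each replicate restrains
`n_positions` solutes `position_spacing` apart, successive replicates shift
the comb by δ = `position_spacing`/`n_replicates`. Seven positions spaced
1 nm over [−3.5, 3.5] with 12 replicates give 84 windows spaced 1/12 nm;
with 20 replicates, 140 windows spaced exactly 0.05 nm. The restraint is
harmonic with k = 2000 kJ mol⁻¹ nm⁻², giving a biased-window standard
deviation σ = √(RT/k) ≈ 0.035 nm at 300 K — about 42% of the 1/12 nm
spacing, so neighbouring histograms overlap.

### The Langevin surrogate

Each window's coordinate evolves by overdamped Langevin dynamics on
G(z) + k/2 (z − z₀)² using the Leimkuhler–Matthews discretisation

    z ← z − (D/RT)(G′ + k(z−z₀)) dt + √(2 D dt) (ξ_prev + ξ)/2 .

Averaging consecutive noises makes the sampled stationary distribution
exact for harmonic potentials and O(dt²) accurate otherwise, which is what
permits a large time step. Time is in reduced units; only the stationary
distribution matters for WHAM, so no mapping to nanoseconds is claimed.

Defaults: D = 1 nm²/time, dt = 2.5×10⁻⁴ (per-step damping
a = Dk dt/RT = 0.2 for k = 2000 at 300 K, window relaxation ≈ 5 steps),
stride 10 (near-independent samples), 300 000 steps per window → 30 000
samples, of which the first third is discarded as equilibration (mirroring
the analyse-the-last-two-thirds convention), leaving 20 000 per window.
Measured checks: flat-surface window variance within 0.5% of RT/k; landmark
recovery scatter ≈ 0.1 kJ/mol over seeds at this size. A stability guard
rejects time steps whose noise displacement √(2 D dt) exceeds
`w_interface`/5. Windows are seeded as `seed + window_index`, so a window's
stream is identical whether sampled alone or in a batch; unbiased (k = 0)
runs require the optional reflecting boundary at ±`z_max` (Boltzmann
statistics on the truncated domain are preserved).

Each window is sampled independently: the original multi-solute trick is a
sampling-efficiency device, and with solutes 1 nm apart the coupling is
negligible, so the surrogate omits it.

## WHAM

The standard self-consistent equations are iterated to a fixed point in the
window free energies f_i, with the unbiased bin probabilities normalised
each sweep and G = −RT ln P; iteration stops when max|Δf_i| < tol
(default 10⁻⁷ kJ/mol, max 10⁵ sweeps; deterministic, f initialised to 0).
Two numerical points matter with stiff restraints:

* **Bin width.** Binned WHAM requires bins comfortably narrower than the
  biased-window σ. With σ = 0.035 nm, 0.05 nm bins distort well depths by
  ~1 kJ/mol (measured against exact iid Boltzmann samples); the default bin
  width is therefore 0.01 nm. Bin width is configurable, and the 0.05 nm
  granularity sometimes quoted for window placement is a placement shift,
  not a histogram requirement.
* **Bin-averaged bias factors.** exp(−U_i/RT) is averaged analytically over
  each bin (an erf expression) instead of evaluated at the bin centre;
  at any resolution comparable to σ the centre-value variant is biased.

Plain fixed-point iteration converges slowly on 84-window instances
(~3×10⁴ sweeps) and can stall on thinned bootstrap resamples. The solver
therefore first maximises the equivalent concave log-likelihood
L(f) = Σᵢ Nᵢ fᵢ/RT − Σ_b H_b ln Σᵢ Nᵢ e^{fᵢ/RT} c_ib with L-BFGS
(deterministic) and then polishes with the fixed-point iteration until the
stated tolerance is met, so the reported solution is still the
self-consistent fixed point. A `warm_start=False` escape hatch runs the
plain iteration only.

Windows must form a connected overlap graph (shared occupied bins);
disconnection is an error naming the gap, weak adjacent overlap a warning.
Bins never visited by any window are left undefined (NaN), never
interpolated, and all downstream consumers tolerate these gaps.

## Referencing, symmetrization, combination

The gas phase is the zero: the unweighted mean of G over the vacuum region
(default |z| ∈ [3.0, 3.5] nm) is subtracted. Because the two interfaces of
the slab are physically equivalent, G(z) and G(−z) are averaged
(idempotent; where only one mirror bin is defined its value is used).

Replicate combination defaults to one pooled WHAM over all windows — the
statistically efficient reading of "one solve over 84 windows".
`combine="mean"` exposes the alternative profile-averaging reading: windows
are partitioned into interleaved offset groups (default 2) that each still
span the full coordinate range, each group is solved and referenced
separately, and the per-bin mean is taken. A literal per-replicate solve is
impossible under this placement scheme — one replicate's windows are 1 nm
apart with σ = 0.035 nm, a disconnected overlap graph — which is why the
groups interleave. Both paths agree within bootstrap error on synthetic
data (tested).

## Uncertainties

Whole windows are resampled with replacement (`n_boot` ≥ 20, default 50,
seeded), WHAM re-solved per resample (warm-started from the full-data
solution, at tolerance max(tol, 10⁻⁵) kJ/mol — the se is a 0.01–1 kJ/mol
quantity), referenced and symmetrized identically, and the per-bin standard
deviation across resamples is reported as `se`. Window-level resampling
mirrors the independently repeated biased runs and is conservative for the
weakly overlapping default grid.

## Landmarks and derived quantities

On the referenced, symmetrized profile (z ≥ 0 half): ΔG_gs is the minimum
over the interface search region (default |z| ∈ [0.8, 2.6] nm; ties break
toward smaller |z|), ΔG_hydr the unweighted mean over the bulk plateau
region (default |z| ≤ 0.7 nm), and ΔG_sl ≡ ΔG_hydr − ΔG_gs, so the additive
identity holds to machine precision — consistent with the published
free-energy tables this analysis mirrors, where the three columns satisfy
the identity exactly. A separate `barrier_max` diagnostic reports any
intervening maximum between the minimum and the bulk region. The region
boundaries are configuration-exposed and logged; where the plateaus are
read is an analysis choice, not a property of the data.

Concentration enhancements are exp(−ΔG/RT) at the profile temperature
(300 K, the thermostat setting — not 298.15 K). Henry's-law constants are
converted at their own reference temperature (conventionally 298.15 K for
compiled values) via H_cc = H_cp·R·T and ΔG_hydr = −RT ln H_cc; both
temperatures are explicit fields, never implicit. Species are classed
hydrophilic iff ΔG_hydr < 0 (exactly 0 → hydrophobic with a warning).

## Validation tolerances

Reference-table comparisons use: 0.01 kJ/mol on the additive identity
(print precision of the two-decimal free energies); 1% relative on
enhancements (±0.005 kJ/mol rounding of ΔG propagated through the
exponential) plus half a unit in the enhancement's own last printed digit
(a value printed "4.8" carries ±0.05 of its own rounding); exact match on
class labels.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the problem — stiff harmonic
biases on a smooth two-plateau surface with interfacial wells, realistic
window counts and sample sizes — so passing tests demonstrate that the
estimator chain (histograms → WHAM → referencing → landmarks) is unbiased
at the 0.1–0.3 kJ/mol level and that its error bars cover. It does not
emulate explicit-solvent physics: no force-field energetics, no capillary
waves or interface roughness, no slow orthogonal degrees of freedom (the
1D dynamics decorrelate in a few steps, where MD may need nanoseconds), no
aqueous reaction chemistry or speciation. Agreement of the full MD-derived
profiles with experiment is a property of the underlying force fields, not
of this analysis code.

## Problem sizes

Default test-suite and pipeline sizes were chosen so a single-CPU run of
the full analysis for one species (84 windows × 300k steps, WHAM, 50
bootstrap resamples) completes in ~15 s and the whole test suite in about a
minute, while keeping landmark recovery error (~0.1 kJ/mol typical, ≤0.26
observed over seeds) well inside the 0.3 kJ/mol validation band.
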